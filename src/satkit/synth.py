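"""Synthetic satellite-genome generator with machine-readable planted truth.

Emulates the statistical structure of satellite repeats in small heath-family
(blueberry-like) plant genomes: tandem arrays of 36-240 bp AT-rich monomers,
two-subunit higher-order repeat (HOR) structure, species-specific
substitution/indel divergence, satellite-like units embedded in LTR- and
TIR-bounded mobile elements flanked by short target-site duplications (TSDs),
and PCR-multimer clone sequences produced by outward-facing primers.

Every generator is seeded and byte-deterministic.  Each planted feature is
recorded in a :class:`PlantedTruth`, the ground-truth oracle that downstream
detection stages are scored against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .seqcore import (
    GenomeFeature,
    Interval,
    Sequence,
    reverse_complement,
    write_gff3,
)

__all__ = [
    "MutationModel",
    "HORSpec",
    "PrimerPair",
    "PlantedTruth",
    "TruthFeature",
    "Placement",
    "make_random_sequence",
    "apply_mutations",
    "build_hor_monomer",
    "build_array",
    "build_te_with_satellite",
    "assemble_chromosome",
    "simulate_clone_set",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class MutationModel:
    """Per-site independent mutation process (star phylogeny from a template).

    All rates are probabilities per template site and must lie in ``[0, 0.5)``.
    Substitutions draw a uniformly random *different* base; insertions add one
    random base after the site; deletions drop the site.
    """

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{name} must be in [0, 0.5), got {v}")


@dataclass
class HORSpec:
    """Ordered subunits making up one monomer.

    ``subunits`` is a list of ``(label, residues)``.  Labels sharing a stem
    before the last dash (``S1-1``, ``S1-2``) are variants of one subunit:
    the second and later occurrences are re-derived from the first by
    applying exactly ``round(variant_divergence * len)`` substitutions at
    random positions, which is how the generator plants internal
    duplications with a well-defined planted divergence.
    """

    subunits: list[tuple[str, str]]
    variant_divergence: float = 0.0

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError("HORSpec requires at least one subunit")
        labels = [lab for lab, _ in self.subunits]
        if len(set(labels)) != len(labels):
            raise ValueError("subunit labels must be unique")
        if not (0.0 <= self.variant_divergence < 0.5):
            raise ValueError("variant_divergence must be in [0, 0.5)")

    @property
    def monomer_length(self) -> int:
        return sum(len(res) for _, res in self.subunits)


@dataclass(frozen=True)
class PrimerPair:
    """Outward-facing primer geometry on the plus strand of one monomer.

    The forward primer occupies ``[forward_start, forward_end)`` and extends
    toward the 3' monomer junction; the reverse primer occupies
    ``[reverse_start, reverse_end)`` on the plus strand and extends leftward
    (toward the 5' junction).  The first amplicon therefore runs from the
    forward primer 5' end across the junction to the reverse primer 5' end:
    ``(monomer_length - forward_start) + reverse_end``.
    """

    forward_start: int
    forward_end: int
    reverse_start: int
    reverse_end: int
    forward_seq: str | None = None
    reverse_seq: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.forward_start < self.forward_end):
            raise ValueError("invalid forward primer interval")
        if not (0 <= self.reverse_start < self.reverse_end):
            raise ValueError("invalid reverse primer interval")


@dataclass
class TruthFeature:
    """One planted feature: located interval, kind, family, free attributes."""

    interval: Interval
    kind: str  # {"array", "monomer", "te", "tsd", "subunit", "ltr", "tir"}
    family: str = ""
    attributes: dict = field(default_factory=dict)


@dataclass
class PlantedTruth:
    """Generator-side ground truth used as the acceptance oracle."""

    features: list[TruthFeature] = field(default_factory=list)

    def of_kind(self, kind: str, family: str | None = None) -> list[TruthFeature]:
        return [
            f
            for f in self.features
            if f.kind == kind and (family is None or f.family == family)
        ]

    def shifted(self, offset: int) -> "PlantedTruth":
        return PlantedTruth(
            [
                TruthFeature(f.interval.shifted(offset), f.kind, f.family, dict(f.attributes))
                for f in self.features
            ]
        )

    def on(self, seq_id: str) -> "PlantedTruth":
        return PlantedTruth(
            [
                TruthFeature(
                    Interval(seq_id, f.interval.start, f.interval.end, f.interval.strand),
                    f.kind,
                    f.family,
                    dict(f.attributes),
                )
                for f in self.features
            ]
        )

    def to_gff3(self, path) -> None:
        write_gff3(
            [
                GenomeFeature(
                    f.interval,
                    f.kind,
                    None,
                    {"Name": f.family or f.kind, **{k: str(v) for k, v in f.attributes.items()}},
                )
                for f in self.features
            ],
            path,
            source="satkit-truth",
        )


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------

def make_random_sequence(
    length: int, gc: float = 0.38, seed: int | np.random.Generator = 0, seq_id: str = "random"
) -> Sequence:
    """I.i.d. sequence with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    return Sequence(seq_id, _BASES[draws].tobytes().decode("ascii"))


def _mutate_residues(residues: str, model: MutationModel, rng: np.random.Generator) -> str:
    """Apply the per-site mutation process; returns mutated residues."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    n = arr.size
    sub_mask = rng.random(n) < model.substitution_rate
    del_mask = rng.random(n) < model.deletion_rate
    ins_mask = rng.random(n) < model.insertion_rate
    # Substitutions: shift each hit by 1-3 positions in base order (mod 4),
    # guaranteeing a different base; N sites are left untouched.
    code = np.full(n, 4, dtype=np.int8)
    for c, b in enumerate(b"ACGT"):
        code[arr == b] = c
    shifts = rng.integers(1, 4, size=n)
    new_code = (code + shifts) % 4
    out = []
    bases = "ACGT"
    for i in range(n):
        ch = residues[i]
        if sub_mask[i] and code[i] != 4:
            ch = bases[new_code[i]]
        if not del_mask[i]:
            out.append(ch)
        if ins_mask[i]:
            out.append(bases[rng.integers(0, 4)])
    if not out:  # pathological all-deleted short input
        out.append(residues[0])
    return "".join(out)


def apply_mutations(seq: Sequence, model: MutationModel) -> Sequence:
    """Mutate a sequence under ``model`` (deterministic for a given seed)."""
    rng = np.random.default_rng(model.seed)
    return Sequence(seq.id, _mutate_residues(seq.residues, model, rng), seq.description)


def exact_substitutions(residues: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct random positions.

    Used for planted subunit variants: a Bernoulli process would make the
    *realized* divergence of a short (10-30 bp) duplication fluctuate widely
    around its nominal value, leaving the planted structure ill-defined;
    an exact count makes the truth the recovery benchmarks score against
    deterministic.
    """
    n = len(residues)
    if not (0 <= n_subs <= n):
        raise ValueError("n_subs must be in [0, len(residues)]")
    pos = rng.choice(n, size=n_subs, replace=False)
    bases = "ACGT"
    out = list(residues)
    for p in pos:
        if out[p] not in bases:
            continue
        shift = int(rng.integers(1, 4))
        out[p] = bases[(bases.index(out[p]) + shift) % 4]
    return "".join(out)


def build_hor_monomer(
    spec: HORSpec, model: MutationModel | None = None
) -> tuple[Sequence, list[tuple[str, Interval]]]:
    """Concatenate subunits into one monomer and return subunit coordinates.

    Later variants of a subunit stem (``S1-2`` after ``S1-1``) are re-derived
    from the first occurrence's residues by exactly
    ``round(variant_divergence * len)`` substitutions, seeded from
    ``model.seed`` so the monomer is reproducible.
    """
    seed = model.seed if model is not None else 0
    rng = np.random.default_rng(seed)
    stems: dict[str, str] = {}
    parts: list[tuple[str, str]] = []
    for label, residues in spec.subunits:
        stem = label.rsplit("-", 1)[0] if "-" in label else label
        if stem in stems and spec.variant_divergence > 0:
            src = stems[stem]
            residues = exact_substitutions(
                src, round(spec.variant_divergence * len(src)), rng
            )
        else:
            stems.setdefault(stem, residues)
        parts.append((label, residues))
    monomer = "".join(res for _, res in parts)
    intervals: list[tuple[str, Interval]] = []
    pos = 0
    for label, res in parts:
        intervals.append((label, Interval("monomer", pos, pos + len(res))))
        pos += len(res)
    return Sequence("monomer", monomer), intervals


def build_array(
    monomer: Sequence, copies: int, model: MutationModel
) -> tuple[Sequence, list[Interval]]:
    """Head-to-tail array of independently mutated copies, plus truth tiling."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = np.random.default_rng(model.seed)
    pieces: list[str] = []
    intervals: list[Interval] = []
    pos = 0
    for _ in range(copies):
        mutated = _mutate_residues(monomer.residues, model, rng)
        pieces.append(mutated)
        intervals.append(Interval(f"{monomer.id}_array", pos, pos + len(mutated)))
        pos += len(mutated)
    return Sequence(f"{monomer.id}_array", "".join(pieces)), intervals


# ---------------------------------------------------------------------------
# Transposable elements carrying satellite units
# ---------------------------------------------------------------------------

def build_te_with_satellite(
    kind: str,
    internal: Sequence,
    sat_units: list[Sequence],
    arrangement: str = "single",
    tsd_length: int = 3,
    seed: int = 0,
    terminal_length: int | None = None,
    family: str = "sat",
    allowed_tsd_lengths: Iterable[int] = (0, 3, 8, 9),
) -> tuple[Sequence, PlantedTruth, int]:
    """Build a mobile element containing satellite-like units.

    ``ltr_retro``
        identical long terminal repeats flank the internal region; the given
        sat unit(s) are embedded inside *each* LTR (solo-LTR-like pattern when
        ``internal`` is short).
    ``tir_dna``
        terminal inverted repeats flank an internal region carrying the sat
        units, tandemly when ``arrangement == "tandem"``.

    Returns ``(element, truth, tsd_length)``; truth coordinates are relative
    to the element.  The TSD itself is created at insertion time by
    :func:`assemble_chromosome` (duplication of the insertion-site k-mer).
    """
    if kind not in {"ltr_retro", "tir_dna"}:
        raise ValueError(f"unknown element kind {kind!r}")
    if not sat_units:
        raise ValueError("sat_units must be non-empty")
    if arrangement not in {"tandem", "single"}:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    if arrangement == "tandem" and len(sat_units) < 2:
        raise ValueError("tandem arrangement requires >= 2 sat units")
    if tsd_length not in set(allowed_tsd_lengths):
        raise ValueError(f"tsd_length {tsd_length} not in allowed set {sorted(set(allowed_tsd_lengths))}")
    rng = np.random.default_rng(seed)
    truth = PlantedTruth()

    if kind == "ltr_retro":
        tl = terminal_length or 300
        unit_block = "".join(u.residues for u in sat_units)
        pad = max(10, (tl - len(unit_block)) // 2)
        left_pad = make_random_sequence(pad, 0.38, rng, "pad").residues
        right_len = max(10, tl - pad - len(unit_block))
        right_pad = make_random_sequence(right_len, 0.38, rng, "pad").residues
        ltr = left_pad + unit_block + right_pad
        element = ltr + internal.residues + ltr
        for ltr_off in (0, len(ltr) + len(internal.residues)):
            truth.features.append(
                TruthFeature(Interval("element", ltr_off, ltr_off + len(ltr)), "ltr", family)
            )
            upos = ltr_off + pad
            for u in sat_units:
                truth.features.append(
                    TruthFeature(Interval("element", upos, upos + len(u)), "monomer", family)
                )
                upos += len(u)
    else:  # tir_dna
        tl = terminal_length or 25
        tir = make_random_sequence(tl, 0.38, rng, "tir").residues
        spacer = 0 if arrangement == "tandem" else 30
        inner_parts: list[str] = []
        unit_spans: list[tuple[int, int]] = []
        pos = 0
        for idx, u in enumerate(sat_units):
            if idx and spacer:
                inner_parts.append(make_random_sequence(spacer, 0.38, rng, "sp").residues)
                pos += spacer
            inner_parts.append(u.residues)
            unit_spans.append((pos, pos + len(u)))
            pos += len(u)
        inner = "".join(inner_parts)
        left_flank = internal.residues[: len(internal.residues) // 2]
        right_flank = internal.residues[len(internal.residues) // 2 :]
        element = tir + left_flank + inner + right_flank + reverse_complement(tir)
        inner_off = tl + len(left_flank)
        truth.features.append(TruthFeature(Interval("element", 0, tl), "tir", family))
        truth.features.append(
            TruthFeature(
                Interval("element", len(element) - tl, len(element)), "tir", family
            )
        )
        for s, e in unit_spans:
            truth.features.append(
                TruthFeature(Interval("element", inner_off + s, inner_off + e), "monomer", family)
            )

    truth.features.append(
        TruthFeature(
            Interval("element", 0, len(element)),
            "te",
            family,
            {"kind": kind, "tsd_length": tsd_length},
        )
    )
    return Sequence(f"{kind}_{family}", element), truth, tsd_length


# ---------------------------------------------------------------------------
# Chromosome assembly
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    """One feature to splice into a chromosome backbone.

    ``position`` is the insertion point on the *original* backbone.  For
    elements carrying a TSD, the ``tsd_length`` bases at the insertion site
    are duplicated on both sides of the element (the biological mechanism),
    so the planted TSD is detectable as an anchored exact flank match.
    """

    sequence: Sequence
    truth: PlantedTruth
    position: int
    strand: str = "+"
    tsd_length: int = 0


def _mirror_truth(truth: PlantedTruth, length: int) -> PlantedTruth:
    """Mirror truth intervals for a reverse-complemented feature sequence."""
    out = PlantedTruth()
    for f in truth.features:
        iv = f.interval
        flipped = Interval(
            iv.seq_id,
            length - iv.end,
            length - iv.start,
            "-" if iv.strand == "+" else "+",
        )
        out.features.append(TruthFeature(flipped, f.kind, f.family, dict(f.attributes)))
    return out


def assemble_chromosome(
    backbone_length: int,
    placements: list[Placement],
    seed: int | np.random.Generator = 0,
    gc: float = 0.38,
    seq_id: str = "chr",
    backbone: str | None = None,
) -> tuple[Sequence, PlantedTruth]:
    """Splice features into a random backbone and lift truth coordinates.

    Placements must be non-overlapping insertion points within the backbone;
    otherwise an error is raised.  A placement with ``tsd_length > 0``
    duplicates the ``tsd_length`` backbone bases immediately right of the
    insertion point on both sides of the element and records ``tsd`` truth
    features.  A pre-built ``backbone`` may be supplied (e.g. to choose an
    insertion site with a particular TSD motif); otherwise a random backbone
    of ``backbone_length`` is drawn from the seed.
    """
    rng = _rng(seed)
    if backbone is None:
        backbone = make_random_sequence(backbone_length, gc, rng, seq_id).residues
    else:
        backbone = backbone.upper()
        backbone_length = len(backbone)
    ordered = sorted(placements, key=lambda p: p.position)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.position < prev.position:
            raise ValueError("overlapping placements")
    positions = [p.position for p in ordered]
    if len(set(positions)) != len(positions):
        raise ValueError("overlapping placements: duplicate insertion points")
    for p in ordered:
        if not (0 <= p.position <= backbone_length - max(p.tsd_length, 1)):
            raise ValueError(f"placement position {p.position} outside backbone")

    pieces: list[str] = []
    truth = PlantedTruth()
    cursor = 0  # on backbone
    out_len = 0  # on assembled chromosome
    for p in ordered:
        pieces.append(backbone[cursor : p.position])
        out_len += p.position - cursor
        cursor = p.position
        feat_seq = p.sequence.residues
        feat_truth = p.truth
        if p.strand == "-":
            feat_seq = reverse_complement(feat_seq)
            feat_truth = _mirror_truth(feat_truth, len(feat_seq))
        if p.tsd_length > 0:
            tsd = backbone[p.position : p.position + p.tsd_length]
            pieces.append(tsd)
            truth.features.append(
                TruthFeature(
                    Interval(seq_id, out_len, out_len + p.tsd_length),
                    "tsd",
                    attributes={"sequence": tsd, "side": "left"},
                )
            )
            out_len += p.tsd_length
        start = out_len
        pieces.append(feat_seq)
        lifted = feat_truth.shifted(start).on(seq_id)
        truth.features.extend(lifted.features)
        out_len += len(feat_seq)
        if p.tsd_length > 0:
            truth.features.append(
                TruthFeature(
                    Interval(seq_id, out_len, out_len + p.tsd_length),
                    "tsd",
                    attributes={"sequence": tsd, "side": "right"},
                )
            )
            # right copy of the TSD comes from the same backbone k-mer, which
            # then continues as ordinary backbone sequence
    pieces.append(backbone[cursor:])
    chrom = "".join(pieces)
    return Sequence(seq_id, chrom), truth


# ---------------------------------------------------------------------------
# PCR clone simulation
# ---------------------------------------------------------------------------

def simulate_clone_set(
    array: Sequence,
    primers: PrimerPair,
    monomer_length: int,
    max_multimer: int,
    model: MutationModel | None = None,
) -> list[Sequence]:
    """Simulate cloned PCR multimers from outward-facing primers on an array.

    For each multimer order ``n = 1..max_multimer`` the amplicon runs from the
    forward primer 5' end across ``n`` monomer junctions to the next reverse
    primer 5' end; its length obeys the ladder law
    ``first_band + (n-1) * monomer_length``.  When the primer sequences are
    given and bind at secondary sites on the first monomer, the off-ladder
    cross-products are emitted as well.  Each product is lightly mutated under
    ``model`` (PCR/sequencing noise).
    """
    L = monomer_length
    if primers.forward_start >= L or primers.reverse_end > L:
        raise ValueError("primer coordinates outside the monomer")
    monomer0 = array.residues[:L]
    fwd_sites = [primers.forward_start]
    rev_sites = [primers.reverse_end]
    if primers.forward_seq:
        if primers.forward_seq.upper() not in array.residues:
            raise ValueError("forward primer sequence not found on the array")
        fwd_sites = _all_occurrences(monomer0, primers.forward_seq.upper())
        if not fwd_sites:
            fwd_sites = [primers.forward_start]
    if primers.reverse_seq:
        # the reverse primer anneals to the plus strand; its 5' end on the
        # plus strand is the *right* edge of its binding site
        site = reverse_complement(primers.reverse_seq.upper())
        if site not in array.residues:
            raise ValueError("reverse primer sequence not found on the array")
        rev_sites = [s + len(site) for s in _all_occurrences(monomer0, site)] or [
            primers.reverse_end
        ]
    rng = np.random.default_rng(model.seed if model else 0)
    clones: list[Sequence] = []
    for n in range(1, max_multimer + 1):
        for f in fwd_sites:
            for r in rev_sites:
                start = f
                end = n * L + r
                if end > len(array.residues):
                    continue
                insert = array.residues[start:end]
                if model is not None:
                    insert = _mutate_residues(insert, model, rng)
                clones.append(Sequence(f"clone_n{n}_f{f}_r{r}", insert))
    if not clones:
        raise ValueError("no amplicon fits on the array; increase array length")
    return clones


def _all_occurrences(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scenario_to_json(params: dict, path) -> None:
    """Dump a scenario's full parameter/seed record as JSON (provenance)."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
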