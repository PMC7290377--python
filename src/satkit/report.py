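"""Copy-number estimation, amplicon-ladder prediction, and family reports.

Copy number follows the read-based quantification rule
``genome_size * genome_proportion / monomer_length`` with the result
truncated (floored) to an integer — truncation, not rounding, is what makes
fractional intermediates such as 2326.7 and 1438.77 reproduce the canonical
integer table exactly.

The amplicon ladder is the characteristic PCR pattern of outward-facing
primers on a tandem array: the first (monomeric) band spans from the forward
primer 5' end across one junction to the reverse primer 5' end, so its size
is ``(monomer_length - forward_start) + reverse_end`` — shorter than the
monomer itself — and every further band adds exactly one monomer length.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

from .families import SatelliteFamily
from .synth import PrimerPair

__all__ = [
    "LadderPrediction",
    "FamilyReport",
    "copy_number",
    "predict_amplicon_ladder",
    "family_report",
]


def copy_number(genome_size: float, proportion: float, monomer_length: float) -> int:
    """Monomer copy number = floor(genome_size * proportion / monomer_length).

    All inputs must be strictly positive.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if proportion <= 0:
        raise ValueError("genome proportion must be > 0")
    if monomer_length <= 0:
        raise ValueError("monomer_length must be > 0")
    return math.floor(genome_size * proportion / monomer_length)


@dataclass
class LadderPrediction:
    """Predicted PCR band sizes for multimer orders 1..n_max."""

    bands: list[int]
    monomer_length: int
    off_ladder: list[int] = field(default_factory=list)

    @property
    def first_band(self) -> int:
        return self.bands[0]


def predict_amplicon_ladder(
    primers: PrimerPair,
    monomer_length: int,
    n_max: int = 4,
    consensus: str | None = None,
) -> LadderPrediction:
    """Predict the amplicon ladder of an outward-facing primer pair.

    Band ``n`` has size ``first_band + (n - 1) * monomer_length`` with
    ``first_band = (monomer_length - forward_start) + reverse_end``.  When
    primer sequences are supplied together with a consensus monomer and a
    primer binds at secondary sites, the cross-products of all site pairs are
    enumerated as off-ladder sizes.

    Raises when the first band cannot physically contain both primers
    (primers overlapping a junction).
    """
    if primers.forward_start >= monomer_length or primers.reverse_end > monomer_length:
        raise ValueError("primer coordinates outside the monomer")
    first = (monomer_length - primers.forward_start) + primers.reverse_end
    plen = 0
    if primers.forward_seq and primers.reverse_seq:
        plen = len(primers.forward_seq) + len(primers.reverse_seq)
    elif primers.forward_seq is None and primers.reverse_seq is None:
        plen = (primers.forward_end - primers.forward_start) + (
            primers.reverse_end - primers.reverse_start
        )
    if first <= plen and plen > 0:
        raise ValueError(
            f"first band ({first} bp) cannot contain both primers ({plen} bp): "
            "primers overlap a monomer junction"
        )
    bands = [first + (n - 1) * monomer_length for n in range(1, n_max + 1)]

    off_ladder: list[int] = []
    if consensus and primers.forward_seq:
        from .synth import _all_occurrences
        from .seqcore import reverse_complement

        fwd_sites = _all_occurrences(consensus.upper(), primers.forward_seq.upper())
        rev_sites = [primers.reverse_end]
        if primers.reverse_seq:
            site = reverse_complement(primers.reverse_seq.upper())
            found = _all_occurrences(consensus.upper(), site)
            if found:
                rev_sites = [s + len(site) for s in found]
        for n in range(1, n_max + 1):
            for f in fwd_sites:
                for r in rev_sites:
                    size = (monomer_length - f) + r + (n - 1) * monomer_length
                    if size > 0 and size not in bands and size not in off_ladder:
                        off_ladder.append(size)
        off_ladder.sort()
    return LadderPrediction(bands, monomer_length, off_ladder)


# ---------------------------------------------------------------------------
# Family report
# ---------------------------------------------------------------------------

@dataclass
class FamilyReport:
    """Aggregated characterization of one satellite family."""

    family: str
    monomer_stats: dict = field(default_factory=dict)
    copy_number: int | None = None
    hor_model: dict | None = None
    specificity: dict | None = None
    te_associations: list = field(default_factory=list)
    distribution: dict | None = None
    ladder: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "FamilyReport":
        return cls(**d)

    def render_text(self) -> str:
        lines = [f"Satellite family {self.family}", "=" * (17 + len(self.family))]
        if self.monomer_stats:
            ms = self.monomer_stats
            lines.append(
                f"monomers: n={ms.get('n', '?')} length {ms.get('length_min', '?')}-"
                f"{ms.get('length_max', '?')} bp, GC {ms.get('gc', float('nan')):.1%}"
            )
        if self.copy_number is not None:
            lines.append(f"estimated copy number: {self.copy_number:,}")
        if self.ladder:
            bands = ", ".join(str(b) for b in self.ladder.get("bands", []))
            lines.append(f"predicted PCR ladder (bp): {bands}")
        if self.hor_model:
            subs = self.hor_model.get("subunits", [])
            desc = " + ".join(s["label"] for s in subs)
            lines.append(f"HOR structure: {desc or 'none'} ({len(subs)} subunit(s))")
        if self.specificity:
            sp = self.specificity
            lines.append(
                f"species specificity: {sp.get('score_points', float('nan')):.1f} points, "
                f"verdict={'species-specific' if sp.get('species_specific') else 'shared'}"
            )
        if self.te_associations:
            for call in self.te_associations:
                lines.append(
                    f"TE association: {call.get('arrangement')} "
                    f"(TSD: {call.get('tsd')})"
                )
        if self.distribution:
            lines.append(
                f"chromosomal distribution: {self.distribution.get('pattern', 'absent')} "
                f"(present on {self.distribution.get('n_present', 0)} chromosome(s))"
            )
        return "\n".join(lines)


def family_report(
    family: SatelliteFamily,
    monomers=None,
    hor_model=None,
    specificity=None,
    te_calls=None,
    distribution=None,
    genome_size: float | None = None,
    n_max_bands: int = 4,
) -> FamilyReport:
    """Assemble the per-family summary from whatever stage outputs exist.

    At least one stage output (or the family's own metadata) must be
    present; missing stages simply leave their section empty.  A family with
    no annotation records reports distribution pattern ``absent``.
    """
    rep = FamilyReport(family.name)
    if monomers:
        from .seqcore import gc_content

        lens = [len(m) for m in monomers]
        gc = sum(gc_content(m) for m in monomers) / len(monomers)
        rep.monomer_stats = {
            "n": len(monomers),
            "length_min": min(lens),
            "length_max": max(lens),
            "gc": gc,
        }
    if genome_size and family.genome_proportion > 0:
        length = family.notes.get("canonical_length", family.monomer_length)
        rep.copy_number = copy_number(genome_size, family.genome_proportion, length)
    if family.primers is not None:
        try:
            ladder = predict_amplicon_ladder(
                family.primers, family.notes.get("canonical_length", family.monomer_length),
                n_max_bands, family.consensus,
            )
            rep.ladder = {
                "bands": ladder.bands,
                "off_ladder": ladder.off_ladder,
            }
        except ValueError:
            rep.ladder = None
    if hor_model is not None:
        rep.hor_model = hor_model.to_dict() if hasattr(hor_model, "to_dict") else hor_model
    if specificity is not None:
        rep.specificity = (
            asdict(specificity) if hasattr(specificity, "__dataclass_fields__") else specificity
        )
    if te_calls:
        rep.te_associations = [
            {
                "arrangement": c.arrangement,
                "tsd": list(c.tsd) if c.tsd else None,
                "n_hits": len(c.sat_hits),
            }
            for c in te_calls
        ]
    if distribution is not None:
        rep.distribution = {
            "pattern": distribution.pattern,
            "n_present": sum(1 for v in distribution.per_chromosome.values() if v > 0),
            "per_chromosome": distribution.per_chromosome,
            "patterns": distribution.patterns,
        }
    else:
        rep.distribution = {"pattern": "absent", "n_present": 0}
    return rep
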