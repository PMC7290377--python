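"""Seeded benchmark scenarios and independent brute-force oracles.

These are the study conditions the package is validated under: small,
fully specified synthetic genomes whose planted truth is known, plus naive
reference implementations (exhaustive window enumeration, recursive optimal
alignment score, additive-tree path distances) used to cross-check the
optimized code paths.  The same scenarios drive the test suite, the
acceptance script and the examples, so every reported rate is reproducible
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .annot import AnnotationRecord, annotate_chromosomes, classify_distribution
from .families import SatelliteFamily
from .hor import decompose_monomer
from .seqcore import Interval, Sequence, reverse_complement
from .synth import (
    MutationModel,
    Placement,
    PlantedTruth,
    TruthFeature,
    _mutate_residues,
    assemble_chromosome,
    build_array,
    build_te_with_satellite,
    make_random_sequence,
)
from .teassoc import classify_association, detect_tsd, scan_similarity

__all__ = [
    "run_te_archetypes",
    "ArchetypeResult",
    "run_hor_replicate",
    "HOR_FAMILY_KINDS",
    "HOR_CONTROL_KINDS",
    "build_annotation_scenario",
    "evaluate_annotation_scenario",
    "brute_wordmatch",
    "brute_windowed_dotplot",
    "brute_global_score",
    "brute_local_score",
    "random_additive_matrix",
]


def _spawn(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, salt]))


# ---------------------------------------------------------------------------
# TE association archetypes
# ---------------------------------------------------------------------------

@dataclass
class ArchetypeResult:
    name: str
    expected_arrangement: str
    observed_arrangement: str
    expected_tsd: int
    observed_tsd: int | None
    ok: bool


def _mutated_units(template: str, n: int, rate: float, rng) -> list[Sequence]:
    model = MutationModel(substitution_rate=rate)
    return [
        Sequence(f"unit{i}", _mutate_residues(template, model, rng)) for i in range(n)
    ]


def _solo_ltr_element(unit: Sequence, rng) -> tuple[Sequence, PlantedTruth]:
    """A lone LTR (recombination leftover) carrying one satellite-like unit."""
    pad_l = make_random_sequence(140, 0.38, rng, "p").residues
    pad_r = make_random_sequence(140, 0.38, rng, "p").residues
    element = pad_l + unit.residues + pad_r
    truth = PlantedTruth(
        [
            TruthFeature(Interval("element", 0, len(element)), "te", "fam", {"kind": "solo_ltr"}),
            TruthFeature(
                Interval("element", len(pad_l), len(pad_l) + len(unit)), "monomer", "fam"
            ),
        ]
    )
    return Sequence("solo_ltr", element), truth


def run_te_archetypes(seed: int) -> list[ArchetypeResult]:
    """One seeded pass over the four satellite-TE association archetypes.

    1. solo-LTR carrying one embedded unit (9 bp TSD)  -> dispersed_in_te
    2. TIR element with 4 tandem units (3 bp TSD)      -> tandem_in_te
    3. full LTR element, one unit per LTR (8 bp TSD)   -> dispersed_in_te
    4. TIR element with 4 tandem units, TAA TSD        -> tandem_in_te
    """
    results: list[ArchetypeResult] = []
    rng = _spawn(seed, 101)
    template = make_random_sequence(154, 0.25, rng, "sat").residues
    query = Sequence("fam", template)

    # -- 1: solo-LTR, one unit, 9 bp TSD -> dispersed
    unit = _mutated_units(template, 1, 0.05, rng)[0]
    element, truth = _solo_ltr_element(unit, rng)
    results.append(
        _run_one_archetype("solo_ltr", element, truth, 9, "dispersed_in_te", query, rng)
    )

    # -- 2: TIR element, 4 tandem units, 3 bp TSD -> tandem
    units = _mutated_units(template, 4, 0.05, rng)
    internal = make_random_sequence(300, 0.38, rng, "int")
    element, truth, _ = build_te_with_satellite(
        "tir_dna", internal, units, "tandem", tsd_length=3, seed=int(rng.integers(2**31)),
        family="fam",
    )
    results.append(
        _run_one_archetype("tir_tandem", element, truth, 3, "tandem_in_te", query, rng)
    )

    # -- 3: full LTR retroelement, one unit per LTR, 8 bp TSD -> dispersed
    unit = _mutated_units(template, 1, 0.05, rng)
    internal = make_random_sequence(900, 0.38, rng, "int")
    element, truth, _ = build_te_with_satellite(
        "ltr_retro", internal, unit, "single", tsd_length=8, seed=int(rng.integers(2**31)),
        family="fam",
    )
    results.append(
        _run_one_archetype("ltr_retro", element, truth, 8, "dispersed_in_te", query, rng)
    )

    # -- 4: TIR element, 4 tandem units, TAA trinucleotide TSD -> tandem
    units = _mutated_units(template, 4, 0.05, rng)
    internal = make_random_sequence(300, 0.38, rng, "int")
    element, truth, _ = build_te_with_satellite(
        "tir_dna", internal, units, "tandem", tsd_length=3, seed=int(rng.integers(2**31)),
        family="fam",
    )
    backbone = make_random_sequence(3000, 0.38, rng, "chr").residues
    pos = backbone.find("TAA", 1200)
    if pos < 0 or pos > 2500:  # vanishingly unlikely at 38% GC; keep it total
        backbone = backbone[:1500] + "TAA" + backbone[1503:]
        pos = 1500
    results.append(
        _run_one_archetype(
            "tir_tandem_taa", element, truth, 3, "tandem_in_te", query, rng,
            backbone=backbone, position=pos,
        )
    )
    return results


def _run_one_archetype(
    name: str,
    element: Sequence,
    truth: PlantedTruth,
    tsd_length: int,
    expected: str,
    query: Sequence,
    rng,
    backbone: str | None = None,
    position: int | None = None,
) -> ArchetypeResult:
    length = 3000
    pos = position if position is not None else 1200 + int(rng.integers(400))
    chrom, chrom_truth = assemble_chromosome(
        length,
        [Placement(element, truth, pos, "+", tsd_length)],
        seed=rng,
        seq_id="chr",
        backbone=backbone,
    )
    te = chrom_truth.of_kind("te")[0].interval
    hits = scan_similarity(query, chrom, min_identity=0.80, min_coverage=0.80)
    tsd = detect_tsd(chrom, te)
    call = classify_association(hits, te, tsd)
    observed_tsd = tsd[0] if tsd else None
    ok = call.arrangement == expected and observed_tsd == tsd_length
    return ArchetypeResult(name, expected, call.arrangement, tsd_length, observed_tsd, ok)


# ---------------------------------------------------------------------------
# HOR decomposition replicates
# ---------------------------------------------------------------------------

#: two-part presets plant a short leading subunit whose echo (15% nominal
#: divergence, exact substitution count) starts the composite second
#: subunit; the three-part preset duplicates a 27 bp subunit at 30%
#: divergence ahead of a 92 bp unrelated subunit.
HOR_FAMILY_KINDS = ("two_subunit_10_27", "two_subunit_17_26", "three_subunit")
HOR_CONTROL_KINDS = ("control_154", "control_70")

_INTER_MONOMER_DIV = 0.05
_N_MONOMERS = 10


def _echo(src: str, divergence: float, rng) -> str:
    from .synth import exact_substitutions

    return exact_substitutions(src, round(divergence * len(src)), rng)


def _hor_template(kind: str, rng) -> tuple[str, list[int]]:
    """Monomer template and the expected internal boundary positions."""
    if kind == "two_subunit_10_27":
        s1 = make_random_sequence(10, 0.20, rng, "s").residues
        echo = _echo(s1, 0.15, rng)
        tail = make_random_sequence(17, 0.20, rng, "t").residues
        return s1 + echo + tail, [10]
    if kind == "two_subunit_17_26":
        s1 = make_random_sequence(17, 0.22, rng, "s").residues
        echo = _echo(s1, 0.15, rng)
        tail = make_random_sequence(9, 0.22, rng, "t").residues
        return s1 + echo + tail, [17]
    if kind == "three_subunit":
        s11 = make_random_sequence(27, 0.18, rng, "s").residues
        s12 = _echo(s11, 0.30, rng)
        s2 = make_random_sequence(92, 0.18, rng, "t").residues
        return s11 + s12 + s2, [len(s11), len(s11) + len(s12)]
    if kind == "control_154":
        return make_random_sequence(154, 0.21, rng, "c").residues, []
    if kind == "control_70":
        return make_random_sequence(70, 0.31, rng, "c").residues, []
    raise ValueError(f"unknown HOR scenario kind {kind!r}")


def run_hor_replicate(kind: str, seed: int, tolerance_bp: int = 2) -> bool:
    """One seeded decomposition replicate; True when the verdict is correct.

    Families succeed when every planted boundary is recovered within
    ``tolerance_bp`` (and no extra boundaries appear); controls succeed when
    the model stays single-subunit.
    """
    rng = _spawn(seed, 202)
    template, expected = _hor_template(kind, rng)
    model = MutationModel(substitution_rate=_INTER_MONOMER_DIV)
    monomers = [
        Sequence(f"m{i}", _mutate_residues(template, model, rng))
        for i in range(_N_MONOMERS)
    ]
    hor = decompose_monomer(monomers)
    found = hor.boundaries
    if not expected:
        return hor.n_subunits == 1
    if len(found) != len(expected):
        return False
    return all(abs(f - e) <= tolerance_bp for f, e in zip(found, expected))


# ---------------------------------------------------------------------------
# Annotation / distribution scenario
# ---------------------------------------------------------------------------

@dataclass
class AnnotationScenario:
    chroms: list[Sequence]
    truth: dict[str, PlantedTruth]  # per chromosome
    families: dict[str, SatelliteFamily]
    expected_pattern: dict[str, str]  # family -> per-chromosome pattern
    chrom_lengths: dict[str, int]


def build_annotation_scenario(
    seed: int,
    n_chrom: int = 12,
    chrom_length: int = 1_100_000,
    divergence: float = 0.05,
) -> AnnotationScenario:
    """A multi-chromosome genome with three planted placement regimes.

    Every chromosome carries: one long central array (30 copies, 154 bp
    monomer), three short arrays at ~5% / ~50% / ~92% of the chromosome
    (5 copies each, 146 bp monomer), and eight isolated TE-borne monomers
    (70 bp) spread end to end with > 100 kb spacing — the central, multisite
    and dispersed regimes respectively.
    """
    rng = _spawn(seed, 303)
    templates = {
        "famCentral": make_random_sequence(154, 0.21, rng, "famCentral").residues,
        "famMultisite": make_random_sequence(146, 0.20, rng, "famMultisite").residues,
        "famDispersed": make_random_sequence(70, 0.31, rng, "famDispersed").residues,
    }
    families = {
        name: SatelliteFamily(
            name, (len(t), len(t)), 0.25, 0.001, consensus=t
        )
        for name, t in templates.items()
    }
    model = MutationModel(substitution_rate=divergence)
    chroms: list[Sequence] = []
    truth: dict[str, PlantedTruth] = {}
    chrom_lengths: dict[str, int] = {}
    for ci in range(n_chrom):
        cid = f"chr{ci + 1:02d}"
        placements: list[Placement] = []

        def array_placement(family: str, copies: int, position: int) -> Placement:
            tmpl = Sequence(family, templates[family])
            arr, intervals = build_array(
                tmpl, copies, MutationModel(substitution_rate=divergence, seed=int(rng.integers(2**31)))
            )
            t = PlantedTruth(
                [TruthFeature(Interval("a", iv.start, iv.end), "monomer", family) for iv in intervals]
                + [TruthFeature(Interval("a", 0, len(arr)), "array", family)]
            )
            return Placement(arr, t, position, "+", 0)

        L = chrom_length
        placements.append(array_placement("famCentral", 30, L // 2))
        for frac in (0.05, 0.50, 0.92):
            pos = int(L * frac) + int(rng.integers(2000))
            placements.append(array_placement("famMultisite", 5, pos))
        # eight isolated TE-borne monomers, > 100 kb apart, spanning the
        # chromosome end to end
        te_positions = np.linspace(0.02 * L, 0.97 * L, 8).astype(int)
        te_positions += rng.integers(-3000, 3000, size=8)
        for pos in te_positions:
            unit = Sequence(
                "famDispersed",
                _mutate_residues(
                    templates["famDispersed"], MutationModel(substitution_rate=divergence),
                    rng,
                ),
            )
            internal = make_random_sequence(400, 0.38, rng, "int")
            element, etruth, _ = build_te_with_satellite(
                "tir_dna", internal, [unit], "single",
                tsd_length=3, seed=int(rng.integers(2**31)), family="famDispersed",
            )
            placements.append(Placement(element, etruth, int(pos), "+", 3))
        # keep insertion points strictly separated
        placements.sort(key=lambda p: p.position)
        chrom, chrom_truth = assemble_chromosome(
            L, placements, seed=rng, gc=0.38, seq_id=cid
        )
        chroms.append(chrom)
        truth[cid] = chrom_truth
        chrom_lengths[cid] = len(chrom)
    expected = {
        "famCentral": "central",
        "famMultisite": "multisite",
        "famDispersed": "dispersed",
    }
    return AnnotationScenario(chroms, truth, families, expected, chrom_lengths)


@dataclass
class AnnotationEvaluation:
    recall: float
    precision: float
    pattern_accuracy: float
    n_truth: int
    n_records: int
    records: list[AnnotationRecord]


def evaluate_annotation_scenario(
    scenario: AnnotationScenario,
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
) -> AnnotationEvaluation:
    """Annotate the scenario genome and score against the planted truth.

    A truth monomer is recovered when a same-family record overlaps at least
    half of it; a record is correct when it overlaps at least half of a
    same-family truth monomer.  Pattern accuracy is the fraction of
    (family, chromosome) pairs classified as designed.
    """
    all_records: list[AnnotationRecord] = []
    for fam in scenario.families.values():
        all_records.extend(annotate_chromosomes(scenario.chroms, fam, min_identity, min_coverage))

    n_truth = 0
    n_recovered = 0
    n_correct = 0
    by_chrom: dict[tuple[str, str], list[AnnotationRecord]] = {}
    for r in all_records:
        by_chrom.setdefault((r.interval.seq_id, r.family), []).append(r)
    for cid, t in scenario.truth.items():
        for fam in scenario.families:
            monomers = t.of_kind("monomer", fam)
            recs = by_chrom.get((cid, fam), [])
            n_truth += len(monomers)
            for m in monomers:
                if any(r.interval.overlap_len(m.interval) >= 0.5 * len(m.interval) for r in recs):
                    n_recovered += 1
    truth_by_key: dict[tuple[str, str], list[TruthFeature]] = {}
    for cid, t in scenario.truth.items():
        for fam in scenario.families:
            truth_by_key[(cid, fam)] = t.of_kind("monomer", fam)
    for r in all_records:
        feats = truth_by_key.get((r.interval.seq_id, r.family), [])
        if any(r.interval.overlap_len(f.interval) >= 0.5 * len(f.interval) for f in feats):
            n_correct += 1

    calls = classify_distribution(all_records, scenario.chrom_lengths)
    n_pairs = 0
    n_match = 0
    for fam, want in scenario.expected_pattern.items():
        for cid in scenario.chrom_lengths:
            n_pairs += 1
            if calls[fam].patterns[cid] == want:
                n_match += 1
    return AnnotationEvaluation(
        recall=n_recovered / n_truth if n_truth else 0.0,
        precision=n_correct / len(all_records) if all_records else 0.0,
        pattern_accuracy=n_match / n_pairs if n_pairs else 0.0,
        n_truth=n_truth,
        n_records=len(all_records),
        records=all_records,
    )


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def _mismatch_grid(a: str, b: str) -> np.ndarray:
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    mism = aa[:, None] != bb[None, :]
    mism |= aa[:, None] == ord("N")
    mism |= bb[None, :] == ord("N")
    return mism


def brute_wordmatch(a: str, b: str, k: int, max_mismatch: int, both_strands: bool = False):
    """Direct enumeration of every (i, j, strand) window; maximal runs of
    qualifying windows on one diagonal are merged into segments.  Returns the
    same (a_start, a_end, b_start, b_end, strand, mismatches) tuples as
    :func:`satkit.tandem.wordmatch_segments`, as a sorted list.

    The window mismatch count ``sum_t mism[i+t, j+t]`` is evaluated as a
    literal sum of ``k`` shifted mismatch grids — a transcription of the
    definition, independent of the per-diagonal cumulative-sum implementation
    it cross-checks.
    """
    out = []
    for strand, bb in (("+", b),) + ((("-", reverse_complement(b)),) if both_strands else ()):
        if k > len(a) or k > len(bb):
            continue
        mism = _mismatch_grid(a, bb)
        counts = np.zeros((len(a) - k + 1, len(bb) - k + 1), dtype=int)
        for t in range(k):
            counts += mism[t : t + counts.shape[0], t : t + counts.shape[1]]
        good = {(int(i), int(j)) for i, j in zip(*np.nonzero(counts <= max_mismatch))}
        for i, j in sorted(good):
            if (i - 1, j - 1) in good:
                continue  # not a run start
            e = 0
            while (i + e + 1, j + e + 1) in good:
                e += 1
            a_s, a_e = i, i + e + k
            b_s, b_e = j, j + e + k
            n_mism = int(mism[np.arange(a_s, a_e), np.arange(b_s, b_e)].sum())
            if strand == "-":
                m = len(b)
                b_s, b_e = m - b_e, m - b_s
            out.append((a_s, a_e, b_s, b_e, strand, n_mism))
    return sorted(out)


def brute_windowed_dotplot(
    a: str, b: str, window: int, threshold: int, match: int = 5, mismatch: int = -4
) -> set[tuple[int, int]]:
    """Direct windowed dotplot: mark every diagonal point covered by some
    full window scoring >= threshold (shifted-grid window sums)."""
    pts: set[tuple[int, int]] = set()
    if window > len(a) or window > len(b):
        return pts
    mism = _mismatch_grid(a, b)
    counts = np.zeros((len(a) - window + 1, len(b) - window + 1), dtype=int)
    for t in range(window):
        counts += mism[t : t + counts.shape[0], t : t + counts.shape[1]]
    scores = match * (window - counts) + mismatch * counts
    for i, j in zip(*np.nonzero(scores >= threshold)):
        for t in range(window):
            pts.add((int(i) + t, int(j) + t))
    return pts


def brute_global_score(a: str, b: str, match: int, mismatch: int, gap: int) -> int:
    """Optimal global alignment score by memoized recursion over the three
    edit moves (independent of the vectorized DP implementation)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0 and j == 0:
            return 0
        best = None
        if i > 0 and j > 0:
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            best = rec(i - 1, j - 1) + s
        if i > 0:
            v = rec(i - 1, j) + gap
            best = v if best is None else max(best, v)
        if j > 0:
            v = rec(i, j - 1) + gap
            best = v if best is None else max(best, v)
        return best

    return rec(len(a), len(b))


def brute_local_score(a: str, b: str, match: int, mismatch: int, gap: int) -> int:
    """Optimal local alignment score as the maximum global score over all
    substring pairs, floored at zero."""
    best = 0
    for i1 in range(len(a) + 1):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b) + 1):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(
                        best, brute_global_score(a[i1:i2], b[j1:j2], match, mismatch, gap)
                    )
    return best


def random_additive_matrix(n_taxa: int, rng) -> tuple[list[str], np.ndarray, set[frozenset]]:
    """A random binary tree with positive branch lengths, returned as its
    additive (path-length) distance matrix plus its non-trivial splits."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # random topology by sequential attachment; edges as an adjacency map
    nodes = [0, 1]
    edges: dict[int, dict[int, float]] = {0: {}, 1: {}}

    def connect(u, v, w):
        edges.setdefault(u, {})[v] = w
        edges.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del edges[u][v]
        del edges[v][u]

    next_id = 2
    connect(0, 1, float(rng.uniform(0.1, 1.0)))
    internal_start = 1000
    edge_list = [(0, 1)]
    for leaf in range(2, n_taxa):
        u, v = edge_list[int(rng.integers(len(edge_list)))]
        w = edges[u][v]
        mid = internal_start + next_id
        split = float(rng.uniform(0.2, 0.8)) * w
        disconnect(u, v)
        connect(u, mid, split)
        connect(mid, v, w - split)
        connect(mid, leaf, float(rng.uniform(0.1, 1.0)))
        edge_list.remove((u, v))
        edge_list.extend([(u, mid), (mid, v), (mid, leaf)])
        next_id += 1
    # path distances between leaves by BFS
    import collections

    n = n_taxa
    D = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        dq = collections.deque([src])
        while dq:
            x = dq.popleft()
            for y, w in edges[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    dq.append(y)
        for dst in range(n):
            D[src, dst] = dist[dst]
    D = (D + D.T) / 2.0  # exact symmetry despite float summation order
    # non-trivial splits: remove each internal edge, collect leaf sides
    splits: set[frozenset] = set()
    for u in list(edges):
        for v in list(edges[u]):
            if u > v:
                continue
            seen = {u}
            dq = collections.deque([u])
            blocked = (u, v)
            while dq:
                x = dq.popleft()
                for y in edges[x]:
                    if (x, y) == blocked or (y, x) == blocked:
                        continue
                    if y not in seen:
                        seen.add(y)
                        dq.append(y)
            side = frozenset(labels[i] for i in seen if i < n)
            if 1 < len(side) < n - 1:
                splits.add(side)
    return labels, D, splits
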