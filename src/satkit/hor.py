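"""Higher-order repeat (HOR) decomposition of satellite monomers.

Many satellite monomers are not elementary: they arose from the duplication
of a shorter motif and now carry an internal direct repeat.  Given a monomer
set, this module scans for internal duplications, fixes subunit boundaries,
classifies diverged subunit variants, and summarizes subunit length and
identity statistics per species.

Detection statistic
-------------------
The visual cue a self-dotplot gives — a short off-diagonal stub at a
sub-monomer lag — is operationalized as an anchored prefix-duplication test
on the *consensus* monomer (majority vote over the monomer set, which
removes most inter-monomer noise):

for each candidate lag ``l`` the leading ``l`` bases are compared with the
following ``l`` bases, and the number of matching sites is referred to an
exact binomial null whose per-site match probability comes from the pooled
monomer base composition (clipped at :data:`P0_CAP`).  This composition
correction matters: satellite monomers are strongly AT-rich, so two
unrelated segments already agree at roughly a third of their sites, and an
uncorrected identity threshold fires on almost every random monomer.  Lags
of at most :data:`SHORT_LAG_MAX` bp carry too few sites for a stable
per-template null and instead use the fixed :data:`SHORT_LAG_IDENTITY`
identity floor (at most 2 mismatches in 10).  The smallest qualifying lag
is called; when no lag qualifies the monomer is elementary (single
subunit).

Model shape
-----------
A called duplication of length ``l`` splits the monomer as follows: when the
echo fills the rest of the monomer (no tail) the two copies *are* the two
subunits; a short duplication (``l`` <= :data:`SHORT_ECHO_MAX`) is reported
as a compact leading subunit followed by a composite subunit that still
contains the echo (the S1 + S2 presentation used for 10-20 bp subunits);
a long duplication with a tail is reported as two repeated variant subunits
ahead of the unrelated remainder (S1-1 + S1-2 + S2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import binom

from .seqcore import Interval, Sequence, global_align
from .tandem import build_consensus, estimate_period, extract_monomers

__all__ = [
    "HORModel",
    "Subunit",
    "SubunitAssignment",
    "decompose_monomer",
    "assign_subunits",
    "assign_subunit_variants",
    "subunit_stats",
    "LAG_ALPHA",
    "LAG_ALPHA_LONG",
    "SHORT_LAG_IDENTITY",
    "SHORT_ECHO_MAX",
]

MIN_LAG = 10  # smallest internal-repeat unit considered, bp
#: lags up to this length use the fixed identity rule instead of the
#: composition test (too few sites for a stable per-template null)
SHORT_LAG_MAX = 12
#: fixed identity floor for short lags: at most 2 mismatches in 10
SHORT_LAG_IDENTITY = 0.8
#: per-lag false-positive budget at subunit-scale lags (13-32 bp, the
#: range where satellite subunits are observed)
LAG_ALPHA = 1e-3
#: stricter budget for longer lags, where sites are plentiful
LAG_ALPHA_LONG = 1e-4
LONG_LAG_MIN = 33
#: composition null is clipped at this per-site match probability; beyond
#: ~62/38 AT skew a per-template plug-in estimate is noise, not signal
P0_CAP = 0.38
#: duplications at most this long are presented as S1 + composite S2
SHORT_ECHO_MAX = 20
#: minimal tail length for a separate trailing subunit
MIN_TAIL = 4
MAX_VARIANT_CLASSES = 3


@dataclass
class Subunit:
    label: str
    length_range: tuple[int, int]
    consensus: str


@dataclass
class HORModel:
    """Ordered subunits of one monomer family plus variant classes."""

    subunits: list[Subunit]
    variant_groups: dict[str, list[str]] = field(default_factory=dict)
    lag: int | None = None
    support: float | None = None
    copy_identity: float | None = None

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    @property
    def boundaries(self) -> list[int]:
        """Internal boundary positions on the model monomer frame."""
        out = []
        pos = 0
        for su in self.subunits[:-1]:
            pos += len(su.consensus)
            out.append(pos)
        return out

    def to_dict(self) -> dict:
        return {
            "subunits": [
                {
                    "label": s.label,
                    "length_range": list(s.length_range),
                    "consensus": s.consensus,
                }
                for s in self.subunits
            ],
            "variant_groups": self.variant_groups,
            "lag": self.lag,
            "support": self.support,
            "copy_identity": self.copy_identity,
        }


@dataclass
class SubunitAssignment:
    """Per-monomer subunit intervals and identities to the subunit consensus."""

    monomer_id: str
    species: str | None
    intervals: dict[str, Interval]
    identities: dict[str, float]
    sequences: dict[str, str]


def _pairwise_match_prob(monomers: list[Sequence]) -> float:
    """Unbiased per-site match probability between unrelated positions,
    pooled over all monomer residues (without-replacement pair counting)."""
    counts = {b: 0 for b in "ACGT"}
    for m in monomers:
        for b in "ACGT":
            counts[b] += m.residues.count(b)
    total = sum(counts.values())
    if total < 2:
        return 0.25
    return sum(c * (c - 1) for c in counts.values()) / (total * (total - 1))


def _prefix_echo_matches(cons: str, lag: int) -> int:
    a, b = cons[:lag], cons[lag : 2 * lag]
    return sum(1 for x, y in zip(a, b) if x == y and x != "N")


def _lag_qualifies(m: int, lag: int, p0: float) -> bool:
    if lag <= SHORT_LAG_MAX:
        return m >= int(np.ceil(SHORT_LAG_IDENTITY * lag))
    budget = LAG_ALPHA if lag < LONG_LAG_MIN else LAG_ALPHA_LONG
    return bool(binom.sf(m - 1, lag, min(p0, P0_CAP)) <= budget)


def decompose_monomer(
    monomers: list[Sequence] | Sequence,
    min_lag: int = MIN_LAG,
) -> HORModel:
    """Detect internal duplication structure in a monomer family.

    Accepts a monomer set (>= 3 monomers) or a single multimeric sequence,
    which is first cut into monomers at its autocorrelation period.  Returns
    a single-subunit model when no lag passes the anchored duplication test
    (see the module docstring for the statistic).
    """
    if isinstance(monomers, Sequence):
        est = estimate_period(monomers, min_period=10)
        if est is None:
            raise ValueError("multimeric input has no detectable period")
        cut, _parts, _ivs = extract_monomers(monomers, est)
        monomers = cut
    if len(monomers) < 3:
        raise ValueError("decompose_monomer requires >= 3 monomers (or a multimer)")
    cons_profile = build_consensus(list(monomers))
    cons = cons_profile.residues
    L = len(cons)
    if L < 2 * min_lag:
        raise ValueError("monomers too short for internal-repeat scanning")
    p0 = _pairwise_match_prob(list(monomers))
    lens = [len(m) for m in monomers]

    hit_lag: int | None = None
    for lag in range(min_lag, L // 2 + 1):
        m = _prefix_echo_matches(cons, lag)
        if _lag_qualifies(m, lag, p0):
            hit_lag = lag
            break
    if hit_lag is None:
        return HORModel(
            [Subunit("S1", (min(lens), max(lens)), cons)],
            {"S1": ["S1"]},
        )

    # refine the boundary: among nearby lags, keep the most identical pair
    best = (-1.0, hit_lag)
    for lag in range(max(min_lag, hit_lag - 2), min(L // 2, hit_lag + 2) + 1):
        ident = _prefix_echo_matches(cons, lag) / lag
        if ident > best[0] + 1e-12:
            best = (ident, lag)
    support, lag = best
    copy_identity = global_align(cons[:lag], cons[lag : 2 * lag]).identity

    tail = L - 2 * lag
    if tail < MIN_TAIL:
        subunits = [
            _make_subunit("S1", monomers, 0, lag),
            _make_subunit("S2", monomers, lag, None),
        ]
        variant_groups = {"S1": ["S1"], "S2": ["S2"]}
    elif lag <= SHORT_ECHO_MAX:
        # short recent echo: compact S1, composite S2 still holding the echo
        subunits = [
            _make_subunit("S1", monomers, 0, lag),
            _make_subunit("S2", monomers, lag, None),
        ]
        variant_groups = {"S1": ["S1"], "S2": ["S2"]}
    else:
        subunits = [
            _make_subunit("S1-1", monomers, 0, lag),
            _make_subunit("S1-2", monomers, lag, 2 * lag),
            _make_subunit("S2", monomers, 2 * lag, None),
        ]
        variant_groups = {"S1": ["S1-1", "S1-2"], "S2": ["S2"]}
    return HORModel(
        subunits, variant_groups, lag=lag, support=support, copy_identity=copy_identity
    )


def _make_subunit(
    label: str, monomers: list[Sequence], start: int, end: int | None
) -> Subunit:
    pieces = []
    for m in monomers:
        e = len(m) if end is None else min(end, len(m))
        if e > start:
            pieces.append(Sequence(f"{m.id}_{label}", m.residues[start:e]))
    cons = build_consensus(pieces)
    lens = [len(p) for p in pieces]
    return Subunit(label, (min(lens), max(lens)), cons.residues)


# ---------------------------------------------------------------------------
# Assignments, variant classes, statistics
# ---------------------------------------------------------------------------

def assign_subunits(
    monomers: list[Sequence],
    model: HORModel,
    species_labels: dict[str, str] | None = None,
) -> list[SubunitAssignment]:
    """Slice each monomer at the model boundaries and score each subunit
    against its consensus.  Boundaries are applied on the monomer frame
    directly (indel-free extraction keeps frames aligned); the final subunit
    absorbs any length difference.
    """
    out: list[SubunitAssignment] = []
    cuts = model.boundaries
    for m in monomers:
        bounds = [0] + [min(b, len(m)) for b in cuts] + [len(m)]
        ivs: dict[str, Interval] = {}
        idents: dict[str, float] = {}
        seqs: dict[str, str] = {}
        for su, (s, e) in zip(model.subunits, zip(bounds, bounds[1:])):
            if e <= s:
                continue
            ivs[su.label] = Interval(m.id, s, e)
            piece = m.residues[s:e]
            seqs[su.label] = piece
            idents[su.label] = global_align(piece, su.consensus).identity
        out.append(
            SubunitAssignment(
                m.id,
                (species_labels or {}).get(m.id),
                ivs,
                idents,
                seqs,
            )
        )
    return out


def assign_subunit_variants(
    assignments: list[SubunitAssignment],
    subunit: str,
    max_classes: int = MAX_VARIANT_CLASSES,
    min_gap: float = 0.05,
) -> dict:
    """Cluster subunit instances into variant classes.

    Average-linkage clustering on pairwise (1 - identity); the class count
    k in 1..max_classes maximizes the mean within-class identity minus the
    mean between-class identity, and a split is only accepted when that gap
    exceeds ``min_gap``.  Returns class membership and per-class consensus.
    """
    instances = [
        (a.monomer_id, a.sequences[subunit])
        for a in assignments
        if subunit in a.sequences
    ]
    if len(instances) < 4:
        raise ValueError("assign_subunit_variants requires >= 4 subunit instances")
    n = len(instances)
    ident = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = global_align(instances[i][1], instances[j][1]).identity
            ident[i, j] = ident[j, i] = v
    dist = 1.0 - ident
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")

    def gap_for(k: int) -> float:
        if k == 1:
            return 0.0
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(set(labels)) < k:
            return -np.inf
        within, between = [], []
        for i in range(n):
            for j in range(i + 1, n):
                (within if labels[i] == labels[j] else between).append(ident[i, j])
        if not within or not between:
            return -np.inf
        return float(np.mean(within) - np.mean(between))

    gaps = {k: gap_for(k) for k in range(1, min(max_classes, n) + 1)}
    best_k = max(gaps, key=lambda k: (gaps[k], -k))
    if gaps[best_k] < min_gap:
        best_k = 1
    if best_k == 1:
        members = {1: [mid for mid, _ in instances]}
        labels = np.ones(n, dtype=int)
    else:
        labels = hierarchy.fcluster(Z, t=best_k, criterion="maxclust")
        members = {}
        for (mid, _seq), lab in zip(instances, labels):
            members.setdefault(int(lab), []).append(mid)
    consensi = {}
    for lab, mids in members.items():
        seqs = [
            Sequence(mid, seq) for (mid, seq), l in zip(instances, labels) if int(l) == lab
        ]
        consensi[lab] = build_consensus(seqs).residues
    return {
        "n_classes": len(members),
        "members": members,
        "consensus": consensi,
        "gap": gaps[best_k] if best_k > 1 else 0.0,
    }


def subunit_stats(assignments: list[SubunitAssignment]) -> pd.DataFrame:
    """Per-species min-max subunit lengths and pairwise identity ranges.

    Species groups with no assigned instances are omitted, not zero-filled.
    """
    rows = []
    species_set = sorted({a.species for a in assignments if a.species is not None})
    if not species_set:
        species_set = [None]
    subunits = sorted({lab for a in assignments for lab in a.sequences})
    for sp in species_set:
        group = [a for a in assignments if a.species == sp]
        for su in subunits:
            seqs = [a.sequences[su] for a in group if su in a.sequences]
            if not seqs:
                continue
            lens = [len(s) for s in seqs]
            idents = []
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    idents.append(global_align(seqs[i], seqs[j]).identity)
            rows.append(
                {
                    "species": sp,
                    "subunit": su,
                    "n": len(seqs),
                    "length_min": min(lens),
                    "length_max": max(lens),
                    "identity_min": min(idents) if idents else np.nan,
                    "identity_max": max(idents) if idents else np.nan,
                }
            )
    return pd.DataFrame(rows)
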