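"""Monomer diversity: progressive MSA, distance matrices, neighbor joining,
and a species-specificity score.

The dendrogram stage deliberately uses canonical neighbor joining rather than
approximate maximum likelihood: the trees are used for qualitative clustering
of satellite monomers, and NJ is deterministic, exactly testable, and
provably inverts additive distance matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .seqcore import (
    DEFAULT_GAP,
    DEFAULT_MATCH,
    DEFAULT_MISMATCH,
    Sequence,
    global_align,
)

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "progressive_msa",
    "nj_tree",
    "species_specificity",
    "SpecificityResult",
    "distance_matrix_from_identity",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances (1 - identity) with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("values must be square and match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)


def distance_matrix_from_identity(labels: list[str], identity: np.ndarray) -> DistanceMatrix:
    d = 1.0 - np.asarray(identity, dtype=float)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------

def _kmer_distance(seqs: list[Sequence], k: int = 5) -> np.ndarray:
    """Shared-k-mer distance used only for the guide tree."""
    sets = [
        {s.residues[i : i + k] for i in range(max(1, len(s) - k + 1))} for s in seqs
    ]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j])) or 1
            d[i, j] = d[j, i] = 1.0 - len(sets[i] & sets[j]) / denom
    return d


def progressive_msa(
    seqs: list[Sequence],
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> list[str]:
    """Deterministic guide-tree progressive alignment.

    Pairwise inputs reduce exactly to :func:`satkit.seqcore.global_align`.
    The guide tree is average-linkage on shared-k-mer distances; profiles are
    merged by a sum-of-pairs global DP under the same scoring.  Returns the
    aligned (gapped) strings in input order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires >= 2 sequences")
    if len(seqs) == 2:
        aln = global_align(seqs[0], seqs[1], match, mismatch, gap)
        return [aln.aligned_a, aln.aligned_b]
    d = _kmer_distance(seqs)
    linkage = hierarchy.linkage(squareform(d, checks=False), method="average")
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [s.residues]) for i, s in enumerate(seqs)
    }
    n = len(seqs)
    for step, (ia, ib, _dist, _cnt) in enumerate(linkage):
        ida, idb = int(ia), int(ib)
        members_a, prof_a = profiles.pop(ida)
        members_b, prof_b = profiles.pop(idb)
        merged = _merge_profiles(prof_a, prof_b, match, mismatch, gap)
        profiles[n + step] = (members_a + members_b, merged)
    (_, (members, profile)), = profiles.items()
    out = [""] * n
    for member, row in zip(members, profile):
        out[member] = row
    return out


def _merge_profiles(
    prof_a: list[str], prof_b: list[str], match: int, mismatch: int, gap: float
) -> list[str]:
    na, nb = len(prof_a[0]), len(prof_b[0])

    def freqs(profile: list[str], length: int) -> tuple[np.ndarray, np.ndarray]:
        f = np.zeros((length, 4))
        arr = np.array([list(row) for row in profile])
        for idx, base in enumerate("ACGT"):
            f[:, idx] = (arr == base).sum(axis=0)
        tot = f.sum(axis=1, keepdims=True)
        nonempty = tot[:, 0] > 0
        tot[tot == 0] = 1.0
        return f / tot, nonempty

    fa, _ = freqs(prof_a, na)
    fb, _ = freqs(prof_b, nb)
    # E[score(x, y)] = P(match) * match + (1 - P(match)) * mismatch
    pmatch = fa @ fb.T
    col_score = pmatch * match + (1.0 - pmatch) * mismatch

    H = np.zeros((na + 1, nb + 1))
    H[0, :] = gap * np.arange(nb + 1)
    H[:, 0] = gap * np.arange(na + 1)
    jj = np.arange(nb + 1, dtype=float)
    for i in range(1, na + 1):
        diag = H[i - 1, :-1] + col_score[i - 1]
        up = H[i - 1, 1:] + gap
        arr = np.empty(nb + 1)
        arr[0] = gap * i
        np.maximum(diag, up, out=arr[1:])
        H[i] = np.maximum.accumulate(arr - gap * jj) + gap * jj
    # traceback, diagonal-first
    i, j = na, nb
    ops: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + col_score[i - 1, j - 1])) < eps:
            ops.append("D")
            i -= 1
            j -= 1
        elif i > 0 and abs(H[i, j] - (H[i - 1, j] + gap)) < eps:
            ops.append("U")
            i -= 1
        else:
            ops.append("L")
            j -= 1
    ops.reverse()
    out_a = [""] * len(prof_a)
    out_b = [""] * len(prof_b)
    ai = bi = 0
    for op in ops:
        if op == "D":
            for r, row in enumerate(prof_a):
                out_a[r] += row[ai]
            for r, row in enumerate(prof_b):
                out_b[r] += row[bi]
            ai += 1
            bi += 1
        elif op == "U":
            for r, row in enumerate(prof_a):
                out_a[r] += row[ai]
            for r in range(len(prof_b)):
                out_b[r] += "-"
            ai += 1
        else:
            for r in range(len(prof_a)):
                out_a[r] += "-"
            for r, row in enumerate(prof_b):
                out_b[r] += row[bi]
            bi += 1
    return out_a + out_b


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    label: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)
    rep: str = ""  # lexicographically smallest tip label underneath

    def tips(self) -> list[str]:
        if self.label is not None:
            return [self.label]
        out: list[str] = []
        for child, _bl in self.children:
            out.extend(child.tips())
        return out

    def newick(self) -> str:
        if self.label is not None:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class Dendrogram:
    """Unrooted NJ tree: newick text, tip splits, negative-branch flag."""

    newick: str
    splits: list[frozenset]
    labels: list[str]
    negative_branch_clamped: bool = False


def nj_tree(d: DistanceMatrix) -> Dendrogram:
    """Canonical neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken toward the pair whose (sorted)
    representative tip labels are lexicographically smallest.  Negative
    branch-length estimates are clamped to zero and flagged.
    """
    if d.n < 3:
        raise ValueError("nj_tree requires >= 3 taxa")
    nodes: list[_Node] = [_Node(label=lab, rep=lab) for lab in d.labels]
    dist = d.values.astype(float).copy()
    active = list(range(d.n))
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        N = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai, aj in itertools.combinations(range(N), 2):
            q = (N - 2) * sub[ai, aj] - r[ai] - r[aj]
            rep = tuple(sorted((nodes[active[ai]].rep, nodes[active[aj]].rep)))
            key = (q, rep)
            if best is None or key < best[0]:
                best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = clamp(0.5 * dij + (r[ai] - r[aj]) / (2 * (N - 2)))
        lj = clamp(dij - (0.5 * dij + (r[ai] - r[aj]) / (2 * (N - 2))))
        new = _Node(
            children=[(nodes[i], li), (nodes[j], lj)],
            rep=min(nodes[i].rep, nodes[j].rep),
        )
        nodes.append(new)
        k = len(nodes) - 1
        dist = np.pad(dist, ((0, 1), (0, 1)))
        for am in range(N):
            m = active[am]
            if m in (i, j):
                continue
            dist[k, m] = dist[m, k] = 0.5 * (sub[ai, am] + sub[aj, am] - dij)
        active = [m for m in active if m not in (i, j)] + [k]

    # closed-form star join of the final three nodes
    a, b, c = active
    dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
    la = clamp(0.5 * (dab + dac - dbc))
    lb = clamp(0.5 * (dab + dbc - dac))
    lc = clamp(0.5 * (dac + dbc - dab))
    root = _Node(
        children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)],
        rep=min(nodes[a].rep, nodes[b].rep, nodes[c].rep),
    )
    newick = root.newick() + ";"

    all_tips = frozenset(d.labels)
    splits: list[frozenset] = []

    def collect(node: _Node) -> frozenset:
        if node.label is not None:
            return frozenset([node.label])
        below = frozenset()
        for child, _bl in node.children:
            tipset = collect(child)
            if 1 < len(tipset) < len(all_tips) - 1:
                splits.append(tipset)
            below |= tipset
        return below

    collect(root)
    return Dendrogram(newick, splits, list(d.labels), clamped)


# ---------------------------------------------------------------------------
# Species specificity
# ---------------------------------------------------------------------------

@dataclass
class SpecificityResult:
    """Within-vs-between species identity contrast plus tree monophyly."""

    score_points: float  # percentage points, within minus between
    monophyletic_species: list[str]
    species_specific: bool
    excluded_species: list[str]  # singleton species left out of the within mean


def species_specificity(
    d: DistanceMatrix,
    species_labels: dict[str, str],
    threshold_points: float = 5.0,
) -> SpecificityResult:
    """Score = mean within-species identity minus mean between-species
    identity, in percentage points.  Verdict "species-specific" requires the
    score to reach ``threshold_points`` AND at least one species to form a
    monophyletic tip cluster in the NJ tree.  Species with a single monomer
    are excluded from the within-species mean and reported.
    """
    labels = d.labels
    species = [species_labels[lab] for lab in labels]
    if len(set(species)) < 2:
        raise ValueError("species_specificity requires >= 2 species")
    identity = 1.0 - d.values
    within: list[float] = []
    between: list[float] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            (within if species[i] == species[j] else between).append(identity[i, j])
    counts: dict[str, int] = {}
    for sp in species:
        counts[sp] = counts.get(sp, 0) + 1
    excluded = sorted(sp for sp, cnt in counts.items() if cnt < 2)
    if not within or not between:
        raise ValueError("need both within- and between-species monomer pairs")
    score = (float(np.mean(within)) - float(np.mean(between))) * 100.0

    tree = nj_tree(d)
    mono: list[str] = []
    all_tips = frozenset(labels)
    for sp, cnt in sorted(counts.items()):
        if cnt < 2:
            continue
        tipset = frozenset(lab for lab in labels if species_labels[lab] == sp)
        if cnt >= len(labels) - 1:
            # complement is a single tip: trivially a clade on an unrooted tree
            mono.append(sp)
            continue
        if any(split == tipset or split == all_tips - tipset for split in tree.splits):
            mono.append(sp)
    verdict = score >= threshold_points and bool(mono)
    return SpecificityResult(score, mono, verdict, excluded)
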