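"""Satellite-TE association: genome similarity scanning, hit clustering,
target-site duplication (TSD) detection, and arrangement classification.

Satellite-like units frequently ride inside mobile elements — embedded in
the long terminal repeats (LTRs) of retrotransposons or carried in tandem
between the terminal inverted repeats (TIRs) of DNA transposons, where the
short direct repeat flanking the element (the TSD) is the hallmark of a
genuine insertion.  This module finds satellite-like sequence genome-wide by
seed-and-extend local alignment, groups the hits into families, reads the
TSD off the element boundaries, and classifies each satellite-element
association as tandem-within-TE, dispersed-within-TE, or standalone array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seqcore import Interval, Sequence, local_align, reverse_complement
from .tandem import ConsensusProfile, build_consensus

__all__ = [
    "SimilarityHit",
    "TEAssociationCall",
    "HitCluster",
    "scan_similarity",
    "cluster_hits",
    "detect_tsd",
    "classify_association",
]

SEED_SIZE = 11  # exact-match seed length for candidate discovery
TANDEM_GAP_FRAC = 0.25  # max inter-hit gap, as a fraction of the query length


@dataclass(frozen=True)
class SimilarityHit:
    """A located, identity- and coverage-scored match of a query monomer."""

    interval: Interval
    identity: float
    coverage: float
    query_id: str

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class HitCluster:
    members: list[int]  # indices into the input hit list
    consensus: str


@dataclass
class TEAssociationCall:
    element: Interval | None
    tsd: tuple[int, str] | None
    sat_hits: list[SimilarityHit]
    arrangement: str  # {tandem_in_te, dispersed_in_te, standalone_array, none}


# ---------------------------------------------------------------------------
# Seed-and-extend similarity scan
# ---------------------------------------------------------------------------

def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer integers and a validity mask (no N inside the window)."""
    L = codes.size
    if L < k:
        return np.array([], dtype=np.int64), np.array([], dtype=bool)
    n = L - k + 1
    vals = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    clean = codes.astype(np.int64).clip(0, 4)
    for t in range(k):
        window = clean[t : t + n]
        vals = vals * 4 + np.where(window == 4, 0, window)
        invalid |= window == 4
    return vals, ~invalid


def _encode(residues: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8).copy()
    out = np.full(arr.shape, 4, dtype=np.int8)
    for code, base in enumerate(b"ACGT"):
        out[arr == base] = code
    return out


class _GenomeIndex:
    """Sorted k-mer index over one genome sequence (built once per scan)."""

    def __init__(self, genome: Sequence, k: int = SEED_SIZE):
        self.k = k
        codes = _encode(genome.residues)
        vals, valid = _kmer_codes(codes, k)
        self.positions = np.flatnonzero(valid)
        kept = vals[self.positions]
        order = np.argsort(kept, kind="stable")
        self.sorted_vals = kept[order]
        self.sorted_pos = self.positions[order]

    def lookup(self, val: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_vals, val, side="left")
        hi = np.searchsorted(self.sorted_vals, val, side="right")
        return self.sorted_pos[lo:hi]


def _candidate_starts(index: _GenomeIndex, query: str, k: int) -> np.ndarray:
    qcodes = _encode(query)
    qvals, qvalid = _kmer_codes(qcodes, k)
    ests = []
    for off in np.flatnonzero(qvalid):
        pos = index.lookup(int(qvals[off]))
        if pos.size:
            ests.append(pos - off)
    if not ests:
        return np.array([], dtype=np.int64)
    return np.sort(np.concatenate(ests))


def _group_candidates(ests: np.ndarray, qlen: int, min_seeds: int = 2) -> list[int]:
    """Cluster estimated query-start positions; one alignment per cluster.

    Estimates are binned (8 bp) and bins carried by fewer than ``min_seeds``
    seed hits are discarded before chaining: isolated chance seeds otherwise
    bridge adjacent tandem copies into one cluster and hide a copy from the
    extension step.  Remaining bins closer than half a query length are
    chained and each chain is summarized by its seed-weighted median.
    """
    if ests.size == 0:
        return []
    bins, counts = np.unique(ests // 8, return_counts=True)
    kept = bins[counts >= min_seeds]
    if kept.size == 0:
        kept = bins[counts == counts.max()]
    keep_mask = np.isin(ests // 8, kept)
    ests = ests[keep_mask]

    def summarize(chunk: np.ndarray) -> list[int]:
        # a single locus cannot spread its start estimates over more than a
        # fraction of the query length; wider chains hide adjacent tandem
        # copies and are split at their largest internal gap
        if chunk[-1] - chunk[0] <= 0.6 * qlen or chunk.size < 2:
            return [int(np.median(chunk))]
        cut = int(np.argmax(np.diff(chunk))) + 1
        return summarize(chunk[:cut]) + summarize(chunk[cut:])

    groups: list[int] = []
    start = 0
    for i in range(1, ests.size + 1):
        if i == ests.size or ests[i] - ests[i - 1] > qlen // 2:
            groups.extend(summarize(ests[start:i]))
            start = i
    return groups


def scan_similarity(
    query: ConsensusProfile | Sequence,
    genome: Sequence,
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    seed_size: int = SEED_SIZE,
    index: "_GenomeIndex | None" = None,
) -> list[SimilarityHit]:
    """Find all matches of a query monomer on both strands of a genome.

    Exact ``seed_size``-mer matches nominate candidate loci; each candidate
    is extended by local alignment of the full query against a padded window
    and kept when alignment identity and query coverage reach the floors.
    Hits on the same strand overlapping by more than half of the shorter hit
    are merged, keeping the best identity.
    """
    qseq = query.as_sequence() if isinstance(query, ConsensusProfile) else query
    if len(qseq) >= len(genome):
        raise ValueError("query must be shorter than the genome sequence")
    idx = index if index is not None else _GenomeIndex(genome, seed_size)
    hits: list[SimilarityHit] = []
    for strand, q in (("+", qseq.residues), ("-", reverse_complement(qseq.residues))):
        ests = _candidate_starts(idx, q, idx.k)
        pad = max(20, len(q) // 5)
        for est in _group_candidates(ests, len(q)):
            lo = max(0, est - pad)
            hi = min(len(genome), est + len(q) + pad)
            if hi - lo < idx.k:
                continue
            window = genome.residues[lo:hi]
            aln = local_align(q, window)
            if aln.b_interval is None:
                continue
            qspan = len(aln.a_interval)
            coverage = qspan / len(q)
            if aln.identity < min_identity or coverage < min_coverage:
                continue
            g_iv = Interval(
                genome.id, lo + aln.b_interval.start, lo + aln.b_interval.end, strand
            )
            hits.append(SimilarityHit(g_iv, aln.identity, coverage, qseq.id))
    return _merge_hits(hits)


def _merge_hits(hits: list[SimilarityHit]) -> list[SimilarityHit]:
    """Merge same-strand hits overlapping > 50% of the shorter hit."""
    hits = sorted(hits, key=lambda h: (h.interval.strand, h.start, -h.identity))
    out: list[SimilarityHit] = []
    for h in hits:
        if out:
            prev = out[-1]
            if prev.interval.strand == h.interval.strand:
                ov = prev.interval.overlap_len(h.interval)
                shorter = min(len(prev.interval), len(h.interval))
                if ov > 0.5 * shorter:
                    if h.identity > prev.identity:
                        out[-1] = h
                    continue
        out.append(h)
    out.sort(key=lambda h: (h.start, h.interval.strand))
    return out


# ---------------------------------------------------------------------------
# Hit clustering (single linkage, identity x length-fraction rule)
# ---------------------------------------------------------------------------

def cluster_hits(
    hits: list[SimilarityHit],
    genome: Sequence | dict[str, Sequence],
    min_identity: float = 0.75,
    min_length_frac: float = 0.75,
) -> list[HitCluster]:
    """Single-linkage clustering of hit sequences.

    Two hits link when their local alignment reaches ``min_identity`` over at
    least ``min_length_frac`` of the *longer* hit.  Each cluster gets a
    majority-rule consensus of its member sequences.
    """
    if not hits:
        raise ValueError("cluster_hits requires at least one hit")
    genomes = genome if isinstance(genome, dict) else {genome.id: genome}
    seqs: list[str] = []
    for h in hits:
        g = genomes[h.interval.seq_id]
        s = g.residues[h.start : h.end]
        if h.interval.strand == "-":
            s = reverse_complement(s)
        seqs.append(s)
    n = len(hits)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            longer = max(len(seqs[i]), len(seqs[j]))
            aln = local_align(seqs[i], seqs[j])
            if aln.a_interval is None:
                continue
            span = max(len(aln.a_interval), len(aln.b_interval))
            if aln.identity >= min_identity and span >= min_length_frac * longer:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[max(pi, pj)] = min(pi, pj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for root in sorted(groups):
        members = groups[root]
        cons = build_consensus(
            [Sequence(f"hit{m}", seqs[m]) for m in members]
        ).residues
        clusters.append(HitCluster(members, cons))
    return clusters


# ---------------------------------------------------------------------------
# Target-site duplication
# ---------------------------------------------------------------------------

def detect_tsd(
    genome: Sequence, element: Interval, max_len: int = 12
) -> tuple[int, str] | None:
    """Longest exact, boundary-anchored direct repeat flanking an element.

    Compares the suffix of the left flank with the prefix of the right flank
    for lengths ``max_len`` down to 2; the first (longest) exact match is the
    TSD.  Returns ``None`` when no match of length >= 2 exists, or (with a
    warning) when the element sits too close to a contig edge.

    The expected false-positive rate of the anchored >= 2 bp rule on random
    flanks is 1/16 per boundary pairing (4^-2), which is why the minimum
    reportable length is 2.
    """
    L = len(genome)
    if element.start < max_len or element.end > L - max_len:
        warnings.warn(
            f"element {element} within {max_len} bp of a contig edge; TSD not assessable",
            stacklevel=2,
        )
        return None
    res = genome.residues
    for t in range(max_len, 1, -1):
        left = res[element.start - t : element.start]
        right = res[element.end : element.end + t]
        if left == right and "N" not in left:
            return t, left
    return None


# ---------------------------------------------------------------------------
# Association classification
# ---------------------------------------------------------------------------

def classify_association(
    sat_hits: list[SimilarityHit],
    element: Interval | None,
    tsd: tuple[int, str] | None = None,
    tandem_gap_frac: float = TANDEM_GAP_FRAC,
) -> TEAssociationCall:
    """Classify a satellite-element configuration.

    * ``tandem_in_te``: >= 2 hits inside the element with every inter-hit gap
      at most ``tandem_gap_frac`` of the query length (adjacent units);
    * ``dispersed_in_te``: >= 1 hit inside the element not meeting the tandem
      rule;
    * ``standalone_array``: no element, >= 2 adjacent hits;
    * ``none`` otherwise.
    """
    hits = sorted(sat_hits, key=lambda h: h.start)
    qlen = int(np.median([len(h.interval) for h in hits])) if hits else 0
    max_gap = tandem_gap_frac * qlen

    def adjacent_pairs(group: list[SimilarityHit]) -> bool:
        if len(group) < 2:
            return False
        gaps = [b.start - a.end for a, b in zip(group, group[1:])]
        return all(g <= max_gap for g in gaps)

    if element is not None:
        inside = [
            h
            for h in hits
            if h.start >= element.start and h.end <= element.end
        ]
        if len(inside) >= 2 and adjacent_pairs(inside):
            arrangement = "tandem_in_te"
        elif inside:
            arrangement = "dispersed_in_te"
        else:
            arrangement = "none"
        return TEAssociationCall(element, tsd, inside, arrangement)
    if len(hits) >= 2 and _has_adjacent_run(hits, max_gap):
        return TEAssociationCall(None, None, hits, "standalone_array")
    return TEAssociationCall(None, None, hits, "none")


def _has_adjacent_run(hits: list[SimilarityHit], max_gap: float) -> bool:
    for a, b in zip(hits, hits[1:]):
        if b.start - a.end <= max_gap:
            return True
    return False
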