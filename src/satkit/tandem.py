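"""Tandem-repeat structure: dotplots, periodicity, monomers, consensus.

The operations here mirror the desk workflow used to characterize satellite
repeats from cloned multimers: mismatch-tolerant word-match dotplots and
windowed (dotmatcher-style) dotplots reveal internal repeat structure,
autocorrelation periodicity recovers the monomer length, arrays and
multimeric clones are cut into monomers against a reference, and a
majority-rule consensus summarizes each monomer set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .seqcore import (
    DEFAULT_GAP,
    DEFAULT_MATCH,
    DEFAULT_MISMATCH,
    Interval,
    Sequence,
    global_align,
    local_align,
    reverse_complement,
)

__all__ = [
    "DotplotSegment",
    "PeriodEstimate",
    "ConsensusProfile",
    "wordmatch_segments",
    "windowed_dotplot",
    "estimate_period",
    "extract_monomers",
    "build_consensus",
    "identity_matrix",
    "segments_to_table",
]

#: dotmatcher-style scoring for windowed_dotplot (DNA +5/-4); the cited
#: window/threshold pair (14/27) then means ">= 7 matches of 14".
WINDOW_MATCH = 5
WINDOW_MISMATCH = -4

#: autocorrelation support below which no period is called
PERIOD_SUPPORT_FLOOR = 0.60
#: sub-multiple resolution: smallest period within this much of the maximum
PERIOD_SUPPORT_SLACK = 0.05


@dataclass(frozen=True)
class DotplotSegment:
    """A maximal diagonal run of mismatch-tolerant word matches."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    mismatches: int

    def __len__(self) -> int:
        return self.a_end - self.a_start


@dataclass(frozen=True)
class PeriodEstimate:
    """Best tandem period: length, autocorrelation support, phase offset."""

    period: int
    support: float
    phase: int


@dataclass
class ConsensusProfile:
    """Majority-rule consensus with per-column agreement fractions."""

    residues: str
    column_support: list[float]
    n_monomers: int
    id: str = "consensus"

    def __len__(self) -> int:
        return len(self.residues)

    def as_sequence(self) -> Sequence:
        return Sequence(self.id, self.residues)


def _codes(x: Sequence | str) -> np.ndarray:
    residues = x.residues if isinstance(x, Sequence) else x.upper()
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8).copy()
    out = np.full(arr.shape, 4, dtype=np.int8)
    for code, base in enumerate(b"ACGT"):
        out[arr == base] = code
    return out


# ---------------------------------------------------------------------------
# Word-match (mismatch-tolerant k-mer) dotplot
# ---------------------------------------------------------------------------

def _diagonal_runs(
    a: np.ndarray, b: np.ndarray, k: int, max_mismatch: int
):
    """Yield (i0, j0, run_start, run_end, mismatch_cumsum) per diagonal.

    A window starting at diagonal offset t is good when it holds
    <= max_mismatch mismatching positions; maximal runs of good windows
    become segments spanning [run_start, run_end + k) diagonal positions.
    """
    n, m = a.size, b.size
    for d in range(-(n - k), m - k + 1):
        i0 = max(0, -d)
        j0 = i0 + d
        length = min(n - i0, m - j0)
        if length < k:
            continue
        mism = (a[i0 : i0 + length] != b[j0 : j0 + length]) | (a[i0 : i0 + length] == 4) | (
            b[j0 : j0 + length] == 4
        )
        cs = np.concatenate([[0], np.cumsum(mism)])
        wind = cs[k:] - cs[:-k]
        good = wind <= max_mismatch
        if not good.any():
            continue
        # maximal runs of consecutive good window starts
        idx = np.flatnonzero(good)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for s, e in zip(starts, ends):
            yield i0, j0, int(idx[s]), int(idx[e]), cs


def wordmatch_segments(
    a: Sequence | str,
    b: Sequence | str,
    word_size: int = 10,
    max_mismatch: int = 2,
    both_strands: bool = False,
) -> list[DotplotSegment]:
    """All maximal diagonal segments whose every ``word_size`` window has at
    most ``max_mismatch`` mismatches (FlexiDot-style word matching).

    Reverse-strand segments (computed against the reverse complement of
    ``b``) are reported in ``b``'s forward coordinates with strand ``-``.
    Returns an empty list when ``word_size`` exceeds either input.
    """
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    if not (0 <= max_mismatch < word_size):
        raise ValueError("max_mismatch must satisfy 0 <= S < word_size")
    ca, cb = _codes(a), _codes(b)
    k = word_size
    if k > ca.size or k > cb.size:
        return []
    segments: list[DotplotSegment] = []
    for i0, j0, s, e, cs in _diagonal_runs(ca, cb, k, max_mismatch):
        segments.append(
            DotplotSegment(
                i0 + s,
                i0 + e + k,
                j0 + s,
                j0 + e + k,
                "+",
                int(cs[e + k] - cs[s]),
            )
        )
    if both_strands:
        rb = _codes(reverse_complement(b if isinstance(b, str) else b.residues))
        m = cb.size
        for i0, j0, s, e, cs in _diagonal_runs(ca, rb, k, max_mismatch):
            # position j' on revcomp(b) covers b coordinate m-1-j'
            b_lo = m - (j0 + e + k)
            b_hi = m - (j0 + s)
            segments.append(
                DotplotSegment(
                    i0 + s,
                    i0 + e + k,
                    b_lo,
                    b_hi,
                    "-",
                    int(cs[e + k] - cs[s]),
                )
            )
    segments.sort(key=lambda t: (t.strand, t.a_start, t.b_start))
    return segments


def segments_to_table(segments: list[DotplotSegment]):
    """Segments as a pandas DataFrame (TSV-ready export)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "a_start": s.a_start,
                "a_end": s.a_end,
                "b_start": s.b_start,
                "b_end": s.b_end,
                "strand": s.strand,
                "mismatches": s.mismatches,
            }
            for s in segments
        ]
    )


# ---------------------------------------------------------------------------
# Windowed (dotmatcher-style) dotplot
# ---------------------------------------------------------------------------

def windowed_dotplot(
    a: Sequence | str,
    b: Sequence | str,
    window: int = 14,
    threshold: int = 27,
    match: int = WINDOW_MATCH,
    mismatch: int = WINDOW_MISMATCH,
) -> sparse.coo_matrix:
    """Sparse boolean matrix of windowed diagonal matches.

    A point ``(i, j)`` is set when *some* full window of ``window`` diagonal
    positions containing it scores at least ``threshold`` under the
    ``match``/``mismatch`` scoring (every position of a qualifying window is
    marked, which is what a drawn dotplot shows).
    """
    ca, cb = _codes(a), _codes(b)
    n, m = ca.size, cb.size
    if window > min(n, m):
        raise ValueError("window exceeds the shorter sequence")
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    w = window
    for d in range(-(n - w), m - w + 1):
        i0 = max(0, -d)
        j0 = i0 + d
        length = min(n - i0, m - j0)
        if length < w:
            continue
        eq = (ca[i0 : i0 + length] == cb[j0 : j0 + length]) & (ca[i0 : i0 + length] != 4)
        cs = np.concatenate([[0], np.cumsum(eq)])
        matches = cs[w:] - cs[:-w]
        scores = match * matches + mismatch * (w - matches)
        good = scores >= threshold
        if not good.any():
            continue
        covered = np.zeros(length, dtype=bool)
        idx = np.flatnonzero(good)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for s, e in zip(starts, ends):
            covered[idx[s] : idx[e] + w] = True
        t = np.flatnonzero(covered)
        rows.append(i0 + t)
        cols.append(j0 + t)
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = np.array([], dtype=int)
        c = np.array([], dtype=int)
    return sparse.coo_matrix(
        (np.ones(r.size, dtype=bool), (r, c)), shape=(n, m)
    )


# ---------------------------------------------------------------------------
# Periodicity
# ---------------------------------------------------------------------------

def estimate_period(
    seq: Sequence | str,
    min_period: int = 2,
    max_period: int | None = None,
) -> PeriodEstimate | None:
    """Autocorrelation period: the fraction of positions matching the base one
    lag away, maximized over lags; sub-multiples resolved by preferring the
    smallest lag whose support is within :data:`PERIOD_SUPPORT_SLACK` of the
    maximum.  Returns ``None`` when the best support falls below
    :data:`PERIOD_SUPPORT_FLOOR`.
    """
    c = _codes(seq)
    L = c.size
    if min_period < 2:
        raise ValueError("min_period must be >= 2")
    hi = max_period if max_period is not None else L // 2
    hi = min(hi, L // 2)
    if hi < min_period:
        return None
    lags = np.arange(min_period, hi + 1)
    support = np.empty(lags.size)
    for idx, p in enumerate(lags):
        eq = (c[:-p] == c[p:]) & (c[:-p] != 4)
        support[idx] = eq.mean()
    best = float(support.max())
    if best < PERIOD_SUPPORT_FLOOR:
        return None
    candidates = np.flatnonzero(support >= best - PERIOD_SUPPORT_SLACK)
    p = int(lags[candidates[0]])
    sup = float(support[candidates[0]])
    return PeriodEstimate(p, sup, _best_phase(c, p))


def _best_phase(c: np.ndarray, p: int) -> int:
    """Offset in [0, p) maximizing mean identity between consecutive copies."""
    L = c.size
    eq = ((c[:-p] == c[p:]) & (c[:-p] != 4)).astype(float)
    best_phase, best_score = 0, -1.0
    for phase in range(p):
        n_copies = (L - phase) // p
        if n_copies < 2:
            continue
        span = (n_copies - 1) * p
        score = float(eq[phase : phase + span].mean())
        if score > best_score + 1e-12:
            best_phase, best_score = phase, score
    return best_phase


# ---------------------------------------------------------------------------
# Monomer extraction
# ---------------------------------------------------------------------------

def extract_monomers(
    seq: Sequence,
    reference: PeriodEstimate | ConsensusProfile | Sequence,
    min_identity: float = 0.5,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> tuple[list[Sequence], list[Sequence], list[Interval]]:
    """Cut an array or multimeric clone into monomers.

    Period mode (``reference`` is a :class:`PeriodEstimate`): the sequence is
    cut at ``phase + n * period``; full-period slices are monomers and any
    incomplete terminal remainder is returned as a partial.

    Consensus mode (``reference`` is a consensus profile or sequence): the
    reference is locally aligned against the sequence, the matched region is
    masked, and the process repeats while the alignment identity stays at or
    above ``min_identity``.  Matched regions covering at least half the
    reference length are monomers; shorter ones are partials.  Raises when no
    alignment reaches ``min_identity`` anywhere.

    Returns ``(monomers, partials, monomer_intervals)`` in sequence order.
    """
    if isinstance(reference, PeriodEstimate):
        return _extract_by_period(seq, reference)
    cons = reference.as_sequence() if isinstance(reference, ConsensusProfile) else reference
    return _extract_by_consensus(seq, cons, min_identity, match, mismatch, gap)


def _extract_by_period(seq: Sequence, est: PeriodEstimate):
    monomers: list[Sequence] = []
    partials: list[Sequence] = []
    intervals: list[Interval] = []
    L, p, phase = len(seq), est.period, est.phase
    if phase > 0:
        partials.append(seq.slice(0, phase, f"{seq.id}_partial_0"))
    idx = 0
    pos = phase
    while pos + p <= L:
        monomers.append(seq.slice(pos, pos + p, f"{seq.id}_m{idx}"))
        intervals.append(Interval(seq.id, pos, pos + p))
        pos += p
        idx += 1
    if pos < L:
        partials.append(seq.slice(pos, L, f"{seq.id}_partial_end"))
    return monomers, partials, intervals


def _extract_by_consensus(
    seq: Sequence, cons: Sequence, min_identity: float, match, mismatch, gap
):
    residues = list(seq.residues)
    hits: list[tuple[Interval, float]] = []
    max_iter = len(seq) // max(1, len(cons)) + 4
    # a hit must cover a meaningful part of the reference: very short local
    # alignments are trivially high-identity and carry no monomer signal
    min_span = max(8, len(cons) // 4)
    for _ in range(max_iter):
        current = Sequence(seq.id, "".join(residues))
        aln = local_align(cons, current, match, mismatch, gap)
        if (
            aln.b_interval is None
            or aln.identity < min_identity
            or len(aln.a_interval) < min_span
        ):
            break
        iv = aln.b_interval
        # local alignment trims mismatching monomer edges; restore them by
        # extending the hit to the uncovered reference span (stopping at
        # sequence bounds or previously extracted regions)
        start, end = iv.start, iv.end
        want_left = aln.a_interval.start
        while want_left > 0 and start > 0 and residues[start - 1] != "N":
            start -= 1
            want_left -= 1
        want_right = len(cons) - aln.a_interval.end
        while want_right > 0 and end < len(residues) and residues[end] != "N":
            end += 1
            want_right -= 1
        hits.append((Interval(seq.id, start, end), aln.identity))
        for i in range(start, end):
            residues[i] = "N"
    hits.sort(key=lambda h: h[0].start)
    monomers: list[Sequence] = []
    partials: list[Sequence] = []
    intervals: list[Interval] = []
    half = 0.5 * len(cons)
    for idx, (iv, _ident) in enumerate(hits):
        piece = seq.slice(iv.start, iv.end, f"{seq.id}_m{idx}")
        if len(iv) >= half:
            monomers.append(piece)
            intervals.append(iv)
        else:
            partials.append(piece)
    if not monomers:
        raise ValueError(
            f"no monomer-scale alignment of the reference reaches identity "
            f"{min_identity} on {seq.id!r}"
        )
    return monomers, partials, intervals


# ---------------------------------------------------------------------------
# Consensus and identity matrices
# ---------------------------------------------------------------------------

_BASE_ORDER = "ACGT"  # fixed tie-break order


def build_consensus(monomers: list[Sequence], id: str = "consensus") -> ConsensusProfile:
    """Majority-rule consensus of a monomer set.

    Monomers are multiply aligned (progressive MSA), then each column takes
    its majority base with ties broken in fixed A<C<G<T order; columns that
    are majority-gap are dropped.  Column support is the fraction of monomers
    agreeing with the consensus base.
    """
    if not monomers:
        raise ValueError("build_consensus requires at least one monomer")
    if len(monomers) == 1:
        m = monomers[0]
        return ConsensusProfile(m.residues, [1.0] * len(m), 1, id)
    from .diversity import progressive_msa

    aligned = progressive_msa(monomers)
    return consensus_from_alignment(aligned, len(monomers), id)


def consensus_from_alignment(
    aligned: list[str], n: int, id: str = "consensus"
) -> ConsensusProfile:
    residues: list[str] = []
    support: list[float] = []
    for col in zip(*aligned):
        gaps = col.count("-")
        if gaps * 2 > len(col):
            continue
        counts = {b: col.count(b) for b in _BASE_ORDER}
        # max() keeps the first maximum, so ties resolve in A<C<G<T order
        best = max(_BASE_ORDER, key=lambda b: counts[b])
        if counts[best] == 0:
            continue  # column is all gaps/N
        residues.append(best)
        support.append(counts[best] / len(col))
    return ConsensusProfile("".join(residues), support, n, id)


def identity_matrix(
    monomers: list[Sequence],
    mask: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Symmetric pairwise identity matrix of a monomer set.

    Without a mask, entries are global-alignment column identities.  With a
    mask (half-open intervals on the consensus frame, e.g. primer regions),
    the monomers are multiply aligned, masked consensus columns are mapped
    through the alignment and excluded from both numerator and denominator,
    and identity is recomputed per pair over the remaining columns (columns
    where both members are gapped are skipped).  Raises when the mask removes
    every column.
    """
    n = len(monomers)
    if n < 2:
        raise ValueError("identity_matrix requires >= 2 monomers")
    out = np.ones((n, n))
    if mask is None:
        for i in range(n):
            for j in range(i + 1, n):
                ident = global_align(monomers[i], monomers[j]).identity
                out[i, j] = out[j, i] = ident
        return out

    from .diversity import progressive_msa

    aligned = progressive_msa(monomers)
    ncols = len(aligned[0])
    # consensus frame: column index -> consensus coordinate (non-majority-gap
    # columns only), mirroring build_consensus's column dropping
    cons_coord = np.full(ncols, -1)
    pos = 0
    for c in range(ncols):
        col = [s[c] for s in aligned]
        if col.count("-") * 2 > len(col):
            continue
        if all(ch in "-N" for ch in col):
            continue
        cons_coord[c] = pos
        pos += 1
    masked_cols = np.zeros(ncols, dtype=bool)
    for lo, hi in mask:
        masked_cols |= (cons_coord >= lo) & (cons_coord < hi)
    keep = ~masked_cols
    if not np.any(keep & (cons_coord >= 0)):
        raise ValueError("mask excludes every consensus column")
    for i in range(n):
        for j in range(i + 1, n):
            cols = 0
            matches = 0
            for c in np.flatnonzero(keep):
                x, y = aligned[i][c], aligned[j][c]
                if x == "-" and y == "-":
                    continue
                cols += 1
                if x == y and x not in "-N":
                    matches += 1
            if cols == 0:
                raise ValueError("mask leaves no comparable columns for a pair")
            out[i, j] = out[j, i] = matches / cols
    return out
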