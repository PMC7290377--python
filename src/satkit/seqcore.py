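"""Shared sequence primitives.

Every stage of the satellite characterization pipeline works on plain
nucleotide strings over the alphabet ``{A, C, G, T, N}``.  This module holds
the :class:`Sequence` container, half-open genomic :class:`Interval`
coordinates, FASTA input/output, simple composition utilities, and the
pairwise alignment engine (global Needleman-Wunsch and local Smith-Waterman
with linear gap costs) used throughout the package.

Conventions
-----------
* Coordinates are 0-based, half-open ``[start, end)`` everywhere inside the
  package.  They are converted to 1-based inclusive only when writing GFF3.
* Alignment identity is the number of matching columns divided by the total
  number of alignment columns; gap columns count against identity.  Published
  repeat-identity values rarely state their denominator, so the package fixes
  this stricter, reproducible definition.
* Traceback ties are broken diagonal-first, then up (gap in the second
  sequence), then left.  This makes every alignment string deterministic.
* ``N`` never matches anything, including another ``N``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Sequence",
    "Interval",
    "AlignmentResult",
    "LocalAlignment",
    "GenomeFeature",
    "read_fasta",
    "write_fasta",
    "gc_content",
    "reverse_complement",
    "global_align",
    "local_align",
    "write_gff3",
    "write_bed",
    "DEFAULT_MATCH",
    "DEFAULT_MISMATCH",
    "DEFAULT_GAP",
]

ALPHABET = frozenset("ACGTN")
#: IUPAC ambiguity codes folded to N on read (everything except ACGT/N).
_AMBIGUOUS = frozenset("RYSWKMBDHVU")

# Default scoring.  The source study never states an alignment scoring
# scheme; these values sit near the tandem-repeat-finder style weight family
# (match 2, heavier mismatch/indel) and are configurable on every call.
DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -3
DEFAULT_GAP = -5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Sequence:
    """An identified nucleotide string over ``{A, C, G, T, N}``.

    Parameters
    ----------
    id :
        Text label (FASTA record id).
    residues :
        Non-empty string; case-folded to upper on construction.
    description :
        Optional free text carried through FASTA round-trips.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int, new_id: str | None = None) -> "Sequence":
        """Return the subsequence ``[start, end)`` as a new :class:`Sequence`."""
        if not (0 <= start < end <= len(self)):
            raise ValueError(f"invalid slice [{start}, {end}) of {self.id!r}")
        return Sequence(new_id or f"{self.id}:{start}-{end}", self.residues[start:end])


@dataclass(frozen=True)
class Interval:
    """Half-open, stranded genomic interval ``[start, end)`` on ``seq_id``."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Interval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end

    def overlap_len(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class AlignmentResult:
    """A gapped pairwise alignment with score and column identity."""

    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


@dataclass
class LocalAlignment(AlignmentResult):
    """Local alignment plus the matched interval on each input."""

    a_interval: Interval | None = None
    b_interval: Interval | None = None


@dataclass
class GenomeFeature:
    """A located feature for GFF3/BED export (annotation records, truth)."""

    interval: Interval
    ftype: str = "region"
    score: float | None = None
    attributes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a (multi-line) FASTA file into a list of :class:`Sequence`.

    Residues are upper-cased and record order is preserved.  IUPAC ambiguity
    codes other than ``N`` are mapped to ``N`` with a warning; any other
    character raises.  An empty file raises.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: list[Sequence] = []
    for rec in records:
        residues = str(rec.seq).upper()
        letters = set(residues)
        ambiguous = letters & _AMBIGUOUS
        if ambiguous:
            warnings.warn(
                f"record {rec.id!r}: IUPAC ambiguity codes {sorted(ambiguous)} mapped to N",
                stacklevel=2,
            )
            residues = residues.translate(
                str.maketrans({c: "N" for c in ambiguous})
            )
        bad = set(residues) - ALPHABET
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains invalid characters: {sorted(bad)}"
            )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(Sequence(rec.id, residues, desc))
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 70) -> None:
    """Write sequences to ``path`` in FASTA, wrapping lines at ``width``."""
    with open(path, "w") as fh:
        for s in seqs:
            header = s.id if not s.description else f"{s.id} {s.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def gc_content(seq: Sequence | str) -> float:
    """Fraction (G+C)/(A+C+G+T); ``N`` is excluded from both sides.

    Raises on an all-N sequence (undefined denominator).
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq.upper()
    gc = residues.count("G") + residues.count("C")
    at = residues.count("A") + residues.count("T")
    if gc + at == 0:
        raise ValueError("GC content undefined: sequence contains no A/C/G/T")
    return gc / (gc + at)


def reverse_complement(seq: Sequence | str) -> Sequence | str:
    """Watson-Crick reverse complement; ``N`` maps to ``N``.

    Returns the same type that was passed in.
    """
    if isinstance(seq, Sequence):
        return Sequence(seq.id, seq.residues.translate(_COMPLEMENT)[::-1], seq.description)
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def _as_residues(x: Sequence | str) -> str:
    return x.residues if isinstance(x, Sequence) else x.upper()


def _as_id(x: Sequence | str, default: str) -> str:
    return x.id if isinstance(x, Sequence) else default


def _encode(residues: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8).copy()
    out = np.full(arr.shape, 4, dtype=np.int8)  # 4 == N / anything else
    for code, base in enumerate(b"ACGT"):
        out[arr == base] = code
    return out


def _match_row(a_code: int, b_codes: np.ndarray, match: int, mismatch: int) -> np.ndarray:
    if a_code == 4:
        return np.full(b_codes.shape, mismatch, dtype=np.int64)
    sub = np.where((b_codes == a_code) & (b_codes != 4), match, mismatch)
    return sub.astype(np.int64)


def _dp_matrix(
    a: np.ndarray, b: np.ndarray, match: int, mismatch: int, gap: int, local: bool
) -> np.ndarray:
    """Fill the full (n+1, m+1) DP score matrix.

    Row recurrence is vectorized: with linear gaps, the left-gap chain
    ``H[i, j] = max_{k<=j} arr[k] + gap*(j-k)`` is a running maximum of
    ``arr[k] - gap*k``.
    """
    n, m = len(a), len(b)
    jj = np.arange(m + 1, dtype=np.int64)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    if not local:
        H[0] = gap * jj
    for i in range(1, n + 1):
        sub = _match_row(int(a[i - 1]), b, match, mismatch)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + gap
        arr = np.empty(m + 1, dtype=np.int64)
        arr[0] = 0 if local else gap * i
        np.maximum(diag, up, out=arr[1:])
        if local:
            np.maximum(arr, 0, out=arr)
        row = np.maximum.accumulate(arr - gap * jj) + gap * jj
        if local:
            np.maximum(row, 0, out=row)
        H[i] = row
    return H


def _traceback(
    H: np.ndarray,
    a: str,
    b: str,
    match: int,
    mismatch: int,
    gap: int,
    local: bool,
    end: tuple[int, int] | None = None,
) -> tuple[str, str, int, int]:
    """Walk back through ``H`` preferring diagonal, then up, then left.

    Returns (aligned_a, aligned_b, start_i, start_j); start indices are the
    0-based positions where the alignment begins on each input.
    """
    i, j = end if end is not None else (len(a), len(b))
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        h = H[i, j]
        if local and h == 0:
            break
        if i > 0 and j > 0:
            ca, cb = a[i - 1], b[j - 1]
            s = match if (ca == cb and ca != "N") else mismatch
            if h == H[i - 1, j - 1] + s:
                out_a.append(ca)
                out_b.append(cb)
                i -= 1
                j -= 1
                continue
        if i > 0 and h == H[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def _column_identity(aligned_a: str, aligned_b: str) -> float:
    if not aligned_a:
        return 0.0
    matches = sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x == y and x not in ("-", "N")
    )
    return matches / len(aligned_a)


def global_align(
    a: Sequence | str,
    b: Sequence | str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment with linear gap costs.

    Deterministic: traceback ties are broken diagonal, then up, then left.
    """
    ra, rb = _as_residues(a), _as_residues(b)
    if not ra or not rb:
        raise ValueError("global_align requires two non-empty sequences")
    H = _dp_matrix(_encode(ra), _encode(rb), match, mismatch, gap, local=False)
    aligned_a, aligned_b, _, _ = _traceback(H, ra, rb, match, mismatch, gap, local=False)
    return AlignmentResult(
        aligned_a,
        aligned_b,
        float(H[-1, -1]),
        _column_identity(aligned_a, aligned_b),
    )


def local_align(
    a: Sequence | str,
    b: Sequence | str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> LocalAlignment:
    """Optimal local (Smith-Waterman) alignment with linear gap costs.

    Returns the alignment plus the matched half-open interval on each input.
    When nothing scores above zero, the result has score 0, empty alignment
    strings and ``None`` intervals.
    """
    ra, rb = _as_residues(a), _as_residues(b)
    if not ra or not rb:
        raise ValueError("local_align requires two non-empty sequences")
    H = _dp_matrix(_encode(ra), _encode(rb), match, mismatch, gap, local=True)
    best = int(H.max())
    if best <= 0:
        return LocalAlignment("", "", 0.0, 0.0, None, None)
    flat = int(np.argmax(H))  # row-major: first (lowest i, then j) maximum
    end = (flat // H.shape[1], flat % H.shape[1])
    aligned_a, aligned_b, i0, j0 = _traceback(
        H, ra, rb, match, mismatch, gap, local=True, end=end
    )
    id_a = _as_id(a, "a")
    id_b = _as_id(b, "b")
    return LocalAlignment(
        aligned_a,
        aligned_b,
        float(best),
        _column_identity(aligned_a, aligned_b),
        Interval(id_a, i0, end[0]),
        Interval(id_b, j0, end[1]),
    )


# ---------------------------------------------------------------------------
# GFF3 / BED writers
# ---------------------------------------------------------------------------

def _gff3_escape(value: str) -> str:
    return (
        str(value)
        .replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def write_gff3(
    features: TypingSequence[GenomeFeature], path: str | Path, source: str = "satkit"
) -> None:
    """Write features as GFF3: 1-based inclusive coordinates at this boundary."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            iv = feat.interval
            score = "." if feat.score is None else f"{feat.score:.4g}"
            attrs = ";".join(
                f"{_gff3_escape(k)}={_gff3_escape(v)}" for k, v in feat.attributes.items()
            ) or "."
            fh.write(
                "\t".join(
                    [
                        iv.seq_id,
                        source,
                        feat.ftype,
                        str(iv.start + 1),
                        str(iv.end),
                        score,
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_bed(features: TypingSequence[GenomeFeature], path: str | Path) -> None:
    """Write features as BED6 (0-based half-open; score scaled to 0-1000)."""
    with open(path, "w") as fh:
        for feat in features:
            iv = feat.interval
            name = str(feat.attributes.get("Name", feat.ftype))
            score = 0 if feat.score is None else int(round(min(1.0, feat.score) * 1000))
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )
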