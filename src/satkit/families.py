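"""Satellite family descriptors and the built-in study-regime presets.

A :class:`SatelliteFamily` bundles a named consensus monomer with the
descriptive metadata the pipeline consumes: monomer length range, GC
content, genome proportion (the fraction of sequenced reads assigned to the
family by read clustering, the basis of copy-number estimation), and the
outward-facing primer geometry used for PCR ladder prediction.

The presets mirror a six-family satellite complement from a diploid
blueberry-type genome of 470 Mb: monomer lengths 36-240 bp, AT-rich
composition (GC 17-41%), and genome proportions from 0.015% to 1%.  They
are read from a packaged JSON-style table and can equally be loaded from a
user TSV/JSON descriptor file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .synth import PrimerPair

__all__ = ["SatelliteFamily", "FAMILY_PRESETS", "load_families", "DEFAULT_GENOME_SIZE"]

#: diploid reference genome size (bp) used for read-based copy numbers
DEFAULT_GENOME_SIZE = 470_000_000


@dataclass
class SatelliteFamily:
    """A named satellite repeat family.

    Parameters
    ----------
    name :
        Family label.
    monomer_length_range :
        (min, max) observed monomer length in bp.
    gc :
        Consensus GC fraction.
    genome_proportion :
        Fraction of the genome occupied (read-cluster based), in [0, 1].
    consensus :
        Consensus monomer residues; may be ``None`` until characterized.
    primers :
        Outward-facing primer geometry, or ``None``.
    """

    name: str
    monomer_length_range: tuple[int, int]
    gc: float
    genome_proportion: float
    consensus: str | None = None
    primers: PrimerPair | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.monomer_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid monomer length range")
        if not (0.0 <= self.genome_proportion <= 1.0):
            raise ValueError("genome proportion must be in [0, 1]")
        if self.consensus is not None:
            clen = len(self.consensus)
            if not (lo * 0.5 <= clen <= hi * 1.5):
                raise ValueError(
                    f"consensus length {clen} inconsistent with range {self.monomer_length_range}"
                )

    @property
    def monomer_length(self) -> int:
        """Canonical single monomer length: the midpoint of the range."""
        lo, hi = self.monomer_length_range
        return (lo + hi) // 2

    def with_consensus(self, consensus: str) -> "SatelliteFamily":
        return replace(self, consensus=consensus)


def _preset(name, lengths, gc, prop, primers=None, **notes) -> SatelliteFamily:
    return SatelliteFamily(name, lengths, gc, prop, None, primers, dict(notes))


#: Built-in family presets.  Primer geometries reproduce the families'
#: first-band PCR product sizes (e.g. a 146 bp monomer amplifying a 119 bp
#: monomeric band because of the primer positions along the consensus).
FAMILY_PRESETS: dict[str, SatelliteFamily] = {
    f.name: f
    for f in [
        _preset(
            "sat146",
            (146, 147),
            0.184,
            0.00999,
            PrimerPair(55, 75, 8, 28),
            first_band=119,
            hor="S1-1 + S1-2 + S2, 26-28 bp duplicated subunits",
        ),
        _preset(
            "sat238",
            (201, 240),
            0.409,
            0.00124,
            PrimerPair(60, 80, 2, 20),
            first_band=198,
            hor="S1 + S2, two long similar subunits",
            canonical_length=238,
        ),
        _preset("sat154", (152, 154), 0.211, 0.0036, PrimerPair(60, 80, 2, 17),
                first_band=111, hor="none", canonical_length=154),
        _preset("sat101", (101, 101), 0.174, 0.0005, None),
        _preset(
            "sat37",
            (36, 38),
            0.199,
            0.00015,
            PrimerPair(10, 30, 8, 28),
            hor="S1 (10 bp) + S2 (26-29 bp)",
        ),
        _preset(
            "sat49",
            (49, 49),
            0.224,
            0.00015,
            PrimerPair(10, 32, 4, 15),
            first_band=54,
            hor="S1 (17 bp) + S2 (26-32 bp)",
        ),
        _preset("sat70", (49, 70), 0.314, 0.00069, None, hor="none"),
    ]
}


def load_families(path: str | Path) -> list[SatelliteFamily]:
    """Load family descriptors from a JSON or tab-separated file.

    JSON: a list of objects with the :class:`SatelliteFamily` field names.
    TSV: columns ``name, length_min, length_max, gc, genome_proportion`` and
    optionally ``consensus``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        out = []
        for row in raw:
            primers = row.get("primers")
            out.append(
                SatelliteFamily(
                    row["name"],
                    tuple(row["monomer_length_range"]),
                    row["gc"],
                    row["genome_proportion"],
                    row.get("consensus"),
                    PrimerPair(**primers) if primers else None,
                )
            )
        return out
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"name", "length_min", "length_max", "gc", "genome_proportion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"family table missing columns: {sorted(missing)}")
    return [
        SatelliteFamily(
            str(row["name"]),
            (int(row["length_min"]), int(row["length_max"])),
            float(row["gc"]),
            float(row["genome_proportion"]),
            str(row["consensus"]) if "consensus" in df.columns and pd.notna(row.get("consensus")) else None,
        )
        for _, row in df.iterrows()
    ]
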