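"""Tabular pairwise-alignment hit records (12-column, outfmt-6 layout).

The column order is the standard tab-separated layout emitted by common
local-alignment search tools::

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore

Coordinates are 1-based inclusive. Several pipeline stages consume this
format: contig contamination triage, peptide-vs-Swiss-Prot hits for
representative selection, and the forward/reverse tables for RBH calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

_DTYPES = {
    "qseqid": str,
    "sseqid": str,
    "pident": float,
    "length": int,
    "mismatch": int,
    "gapopen": int,
    "qstart": int,
    "qend": int,
    "sstart": int,
    "send": int,
    "evalue": float,
    "bitscore": float,
}


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular pairwise-alignment result."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(
                f"hit {self.qseqid}->{self.sseqid}: qstart {self.qstart} > qend {self.qend}"
            )
        if self.evalue < 0:
            raise ValueError(f"hit {self.qseqid}->{self.sseqid}: negative e-value")
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(
                f"hit {self.qseqid}->{self.sseqid}: identity {self.pident} outside [0,100]"
            )

    def to_row(self) -> str:
        return "\t".join(
            [
                self.qseqid,
                self.sseqid,
                f"{self.pident:.2f}",
                str(self.length),
                str(self.mismatch),
                str(self.gapopen),
                str(self.qstart),
                str(self.qend),
                str(self.sstart),
                str(self.send),
                f"{self.evalue:.2e}",
                f"{self.bitscore:.1f}",
            ]
        )


class HitTableFormatError(ValueError):
    """Raised for malformed hit-table rows, carrying the 1-based line number."""


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tab-separated hit table into a typed DataFrame.

    Raises :class:`HitTableFormatError` with the offending line number for
    rows that do not have exactly 12 tab-separated fields or whose numeric
    fields fail to parse.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitTableFormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                rows.append(
                    {col: _DTYPES[col](val) for col, val in zip(HIT_COLUMNS, fields)}
                )
            except ValueError as exc:
                raise HitTableFormatError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _DTYPES.items()})
    return pd.DataFrame(rows)


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(hit.to_row() + "\n")


def hits_from_frame(df: pd.DataFrame) -> list[HitRecord]:
    return [HitRecord(**{c: row[c] for c in HIT_COLUMNS}) for _, row in df.iterrows()]
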