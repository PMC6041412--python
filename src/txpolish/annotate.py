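"""Reciprocal-best-hit identification and functional annotation transfer.

An RBH pair (q, s) between a predicted peptide set and a reference
proteome requires that s is q's best-scoring hit in the forward search and
q is s's best-scoring hit in the reverse search. Best hits are extracted
per query by maximum bitscore; a bitscore tie across *different* subjects
voids the query (conservative — an ambiguous best hit is not an ortholog
call), while multiple HSPs to the same subject collapse to the
highest-scoring one.

Functional descriptions are transferred from the reference gene table onto
the RBH peptides; several reference proteomes can be laid side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "BestHitMap",
    "RbhPair",
    "best_hits",
    "reciprocal_best_hits",
    "transfer_annotation",
    "combine_references",
]


@dataclass
class BestHitMap:
    """Per-query best subject with its score; tie-voided queries tracked separately."""

    hits: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    voided: set[str] = field(default_factory=set)

    def __getitem__(self, query: str) -> tuple[str, float, float]:
        return self.hits[query]

    def __contains__(self, query: str) -> bool:
        return query in self.hits

    def __len__(self) -> int:
        return len(self.hits)


@dataclass(frozen=True)
class RbhPair:
    query: str
    subject: str
    forward_bitscore: float
    reverse_bitscore: float


def best_hits(
    hit_table: pd.DataFrame, evalue_max: float | None = None
) -> BestHitMap:
    """Extract the best hit per query from a 12-column hit table.

    ``evalue_max`` optionally pre-filters rows (off by default; no
    threshold is applied before best-hit extraction unless requested).
    """
    result = BestHitMap()
    if hit_table.empty:
        return result
    df = hit_table
    if evalue_max is not None:
        df = df[df["evalue"] <= evalue_max]
    # collapse multiple HSPs to the same subject first
    idx = df.groupby(["qseqid", "sseqid"])["bitscore"].idxmax()
    collapsed = df.loc[idx]
    for query, group in collapsed.groupby("qseqid"):
        top = group["bitscore"].max()
        leaders = group[group["bitscore"] == top]
        if len(leaders) > 1:
            result.voided.add(str(query))
            continue
        row = leaders.iloc[0]
        result.hits[str(query)] = (
            str(row["sseqid"]),
            float(row["bitscore"]),
            float(row["evalue"]),
        )
    return result


def reciprocal_best_hits(forward: BestHitMap, reverse: BestHitMap) -> list[RbhPair]:
    """Pairs (q, s) with forward[q] = s and reverse[s] = q, sorted by query id."""
    pairs: list[RbhPair] = []
    for query in sorted(forward.hits):
        subject, fwd_bit, _ = forward.hits[query]
        if subject in reverse and reverse.hits[subject][0] == query:
            pairs.append(
                RbhPair(query, subject, fwd_bit, reverse.hits[subject][1])
            )
    return pairs


def transfer_annotation(
    rbh_pairs: Sequence[RbhPair],
    functions: Mapping[str, str] | pd.DataFrame,
    go_terms: Mapping[str, str] | None = None,
    reference_name: str = "reference",
) -> pd.DataFrame:
    """One annotation row per RBH peptide; missing reference entries give blanks.

    ``functions`` maps reference gene id to its description (or a
    two-column DataFrame). Optional ``go_terms`` (peptide id -> GO string,
    a ready-made assignment) is merged in as an extra column.
    """
    if isinstance(functions, pd.DataFrame):
        functions = dict(zip(functions.iloc[:, 0].astype(str), functions.iloc[:, 1].astype(str)))
    rows = []
    missing: list[str] = []
    for pair in rbh_pairs:
        desc = functions.get(pair.subject)
        if desc is None:
            missing.append(pair.subject)
            desc = ""
        row = {
            "peptide": pair.query,
            f"{reference_name}_gene": pair.subject,
            f"{reference_name}_description": desc,
        }
        if go_terms is not None:
            row["go_terms"] = go_terms.get(pair.query, "")
        rows.append(row)
    df = pd.DataFrame(rows)
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "%d RBH subjects missing from functional table (e.g. %s)",
            len(missing),
            missing[:3],
        )
    return df


def combine_references(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Side-by-side annotation columns from several reference proteomes,
    outer-joined on the peptide id."""
    combined: pd.DataFrame | None = None
    for _, table in tables.items():
        if table.empty:
            continue
        combined = (
            table
            if combined is None
            else combined.merge(table, on="peptide", how="outer")
        )
    if combined is None:
        return pd.DataFrame(columns=["peptide"])
    return combined.sort_values("peptide").reset_index(drop=True)
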