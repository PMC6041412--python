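"""Tissue presence/absence calling and Venn partitioning of a count matrix.

A transcript is *present* in a tissue when its read count reaches the
detection threshold (default: at least 1 read — the count matrix is
produced upstream with multi-mapped reads included, so a single assigned
read marks detection). Each transcript present somewhere is assigned to
exactly one Venn region: the subset of tissues in which it is present.
With k tissues there are 2^k - 1 non-empty regions; transcripts absent
everywhere are tallied separately so the partition always conserves the
transcript total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "VennPartition",
    "presence",
    "venn_partition",
    "tissue_specific_counts",
    "read_count_matrix",
    "write_partition_tsv",
]


@dataclass
class VennPartition:
    """Region sizes of the tissue presence/absence set system.

    ``regions`` maps each non-empty tissue subset (as a frozenset of
    labels) to its transcript count; subsets never observed are absent
    (count zero). ``n_absent`` counts transcripts present in no tissue.
    """

    tissues: tuple[str, ...]
    regions: dict[frozenset, int] = field(default_factory=dict)
    n_absent: int = 0

    @property
    def n_present(self) -> int:
        return sum(self.regions.values())

    def region(self, *tissues: str) -> int:
        return self.regions.get(frozenset(tissues), 0)

    def region_label(self, subset: frozenset) -> str:
        return "+".join(t for t in self.tissues if t in subset)


def presence(matrix: pd.DataFrame, threshold: float = 1) -> pd.DataFrame:
    """Boolean presence matrix: cell true iff count >= threshold.

    A threshold of 0 marks everything present, zeros included — a
    documented edge, not an error.
    """
    if (matrix.values < 0).any():
        raise ValueError("count matrix contains negative values")
    return matrix >= threshold


def venn_partition(present: pd.DataFrame) -> VennPartition:
    """Assign each transcript to the region matching its presence set."""
    tissues = tuple(str(c) for c in present.columns)
    if not tissues:
        raise ValueError("at least one tissue is required")
    part = VennPartition(tissues=tissues)
    values = present.values.astype(bool)
    for row in values:
        subset = frozenset(t for t, flag in zip(tissues, row) if flag)
        if subset:
            part.regions[subset] = part.regions.get(subset, 0) + 1
        else:
            part.n_absent += 1
    return part


def tissue_specific_counts(
    partition: VennPartition,
) -> tuple[dict[str, int], tuple[str, int], tuple[str, int]]:
    """Exclusive transcript count per tissue, plus (min tissue, max tissue).

    The exclusive count of a tissue is the size of its singleton region.
    Ties for min/max resolve to the first tissue in column order.
    """
    exclusive = {t: partition.region(t) for t in partition.tissues}
    min_tissue = min(exclusive, key=lambda t: (exclusive[t], partition.tissues.index(t)))
    max_tissue = max(
        exclusive, key=lambda t: (exclusive[t], -partition.tissues.index(t))
    )
    return exclusive, (min_tissue, exclusive[min_tissue]), (max_tissue, exclusive[max_tissue])


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """TSV with a header row of tissue labels and transcript ids in column 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.shape[1] == 0:
        raise ValueError(f"{path}: empty count matrix")
    return df


def write_partition_tsv(partition: VennPartition, path: str | Path) -> None:
    """Region-count table; subsets encoded as tissue labels joined by '+'."""
    with open(path, "w") as fh:
        fh.write("region\tcount\n")
        ordered = sorted(
            partition.regions.items(),
            key=lambda kv: (len(kv[0]), partition.region_label(kv[0])),
        )
        for subset, count in ordered:
            fh.write(f"{partition.region_label(subset)}\t{count}\n")
        fh.write(f"(absent)\t{partition.n_absent}\n")
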