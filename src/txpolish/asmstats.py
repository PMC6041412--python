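"""Assembly statistics: the Nx family and expression-weighted ExNy.

Nx is the length of the contig at which the cumulative sum of
descending-sorted contig lengths first reaches x% of the total assembly
length (>= at the boundary, the standard convention). ExNy (e.g. E90N50)
restricts the Nx computation to the smallest set of most highly expressed
contigs that accounts for E% of total expression, so it reflects the
continuity of the expressed fraction of the assembly rather than of every
assembled fragment. Expression units are taken as given (counts or TPM);
ExNy is invariant to rescaling the expression vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, median
from typing import Mapping

__all__ = ["nx", "exn", "expressed_subset", "assembly_summary", "AssemblySummary"]


def nx(lengths: Mapping[str, int] | list[int], x: float) -> int:
    """Nx of a length set: smallest length L such that contigs >= L cover x% of total."""
    if isinstance(lengths, Mapping):
        values = list(lengths.values())
    else:
        values = list(lengths)
    if not values:
        raise ValueError("Nx of an empty length set is undefined")
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    if any(v < 1 for v in values):
        raise ValueError("contig lengths must be positive integers")
    values.sort(reverse=True)
    total = sum(values)
    threshold = x / 100.0 * total
    cum = 0
    for length in values:
        cum += length
        if cum >= threshold:
            return length
    return values[-1]  # unreachable for x <= 100


def expressed_subset(
    lengths: Mapping[str, int], expression: Mapping[str, float], e: float
) -> list[str]:
    """The smallest prefix of contigs, by descending expression, covering e% of expression.

    Ties in expression break by length descending, then id ascending, for
    determinism.
    """
    if not 0 < e <= 100:
        raise ValueError(f"e must be in (0, 100], got {e}")
    unknown = set(expression) - set(lengths)
    if unknown:
        raise ValueError(f"expression ids absent from length set: {sorted(unknown)[:5]}")
    total = sum(expression.values())
    if total <= 0:
        raise ValueError("total expression must be positive for ExNy")
    if any(v < 0 for v in expression.values()):
        raise ValueError("expression values must be non-negative")
    order = sorted(
        expression, key=lambda cid: (-expression[cid], -lengths[cid], cid)
    )
    threshold = e / 100.0 * total
    prefix: list[str] = []
    cum = 0.0
    for cid in order:
        prefix.append(cid)
        cum += expression[cid]
        if cum >= threshold:
            break
    return prefix


def exn(
    lengths: Mapping[str, int],
    expression: Mapping[str, float],
    e: float,
    x: float,
) -> int:
    """ExNy: Nx over the smallest most-expressed subset covering e% of expression."""
    subset = expressed_subset(lengths, expression, e)
    return nx({cid: lengths[cid] for cid in subset}, x)


@dataclass(frozen=True)
class AssemblySummary:
    count: int
    total_bp: int
    mean_length: float
    median_length: float
    nx_curve: dict[int, int]  # x in 10..90 step 10

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "total_bp": self.total_bp,
            "mean_length": self.mean_length,
            "median_length": self.median_length,
            "nx_curve": {f"N{x}": v for x, v in sorted(self.nx_curve.items())},
        }


def assembly_summary(lengths: Mapping[str, int] | list[int]) -> AssemblySummary:
    """Basic assembly summary: contig count, total bp, mean/median length, Nx curve."""
    values = list(lengths.values()) if isinstance(lengths, Mapping) else list(lengths)
    if not values:
        raise ValueError("cannot summarize an empty assembly")
    return AssemblySummary(
        count=len(values),
        total_bp=sum(values),
        mean_length=mean(values),
        median_length=float(median(values)),
        nx_curve={x: nx(values, x) for x in range(10, 100, 10)},
    )
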