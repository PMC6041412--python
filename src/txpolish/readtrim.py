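"""Paired-end read quality trimming.

Implements the trimming semantics used to clean the sequencing libraries
before assembly: adapter clipping (simple-mode local alignment, scored
+0.6 per match / -3.0 per mismatch, seeded by a 16-mer), a sliding-window
quality clip (window 4, mean Phred < 15), a minimum-length filter
(100 nt), and dropping of pairs in which only one mate survives.

The window rule truncates a read at the start of the first window,
scanning 5'->3', whose mean quality drops below the threshold. Trailing
sub-windows shorter than the window length (including reads shorter than
the window) are evaluated as windows of their own length.

Only Phred+33 encoded FASTQ is accepted; files whose qualities decode to
values above 41 with many characters in the Phred+64 range are rejected
rather than silently mis-decoded.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "QualRead",
    "TrimParams",
    "TrimStats",
    "sliding_window_trim",
    "clip_adapter",
    "filter_pairs",
    "trim_pairs",
    "read_fastq",
    "write_fastq",
    "trim_files",
]

_SEED_LEN = 16


class FastqFormatError(ValueError):
    pass


@dataclass(frozen=True)
class QualRead:
    """A read with per-base Phred qualities; mate is 1 or 2."""

    id: str
    sequence: str
    qualities: tuple[int, ...]
    mate: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FastqFormatError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if any(q < 0 for q in self.qualities):
            raise FastqFormatError(f"read {self.id}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)

    def prefix(self, n: int) -> "QualRead":
        return replace(self, sequence=self.sequence[:n], qualities=self.qualities[:n])


@dataclass(frozen=True)
class TrimParams:
    """Trimming thresholds; defaults mirror the published protocol."""

    window: int = 4
    mean_q: float = 15.0
    min_len: int = 100
    adapter_seed_mismatches: int = 2
    palindrome_threshold: float = 30.0  # retained for interface fidelity; unused
    simple_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass
class TrimStats:
    pairs_in: int = 0
    pairs_out: int = 0
    pairs_dropped: int = 0
    bases_in: int = 0
    bases_out: int = 0
    reads_adapter_clipped: int = 0
    reads_quality_trimmed: int = 0

    @property
    def bases_trimmed(self) -> int:
        return self.bases_in - self.bases_out

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["bases_trimmed"] = self.bases_trimmed
        return d


def sliding_window_trim(read: QualRead, params: TrimParams = TrimParams()) -> QualRead:
    """Clip a read at the first window whose mean quality drops below threshold.

    Windows start at every position; a window extends ``params.window``
    bases or to the read end, whichever is shorter, so trailing
    sub-windows and reads shorter than the window are evaluated as
    windows of their own length. The mean comparison is strict (<).
    """
    q = read.qualities
    n = len(q)
    w = params.window
    for start in range(n):
        window = q[start : start + w]
        if sum(window) / len(window) < params.mean_q:
            return read.prefix(start)
    return read


def _overlap_score(read_seq: str, adapter: str, offset: int) -> tuple[float, int]:
    """Score the ungapped alignment of the adapter starting at read offset.

    Returns (score, overlap_length); the adapter may run off the 3' end of
    the read. Match +0.6, mismatch -3.0, no gaps.
    """
    overlap = min(len(adapter), len(read_seq) - offset)
    score = 0.0
    mismatches_total = 0
    for i in range(overlap):
        if read_seq[offset + i] == adapter[i]:
            score += 0.6
        else:
            score -= 3.0
            mismatches_total += 1
    return score, overlap


def _has_seed(read_seq: str, adapter: str, offset: int, max_mismatch: int) -> bool:
    """True if some 16-mer of the aligned overlap has <= max_mismatch mismatches.

    For overlaps shorter than 16 nt the whole overlap serves as the seed;
    such short matches can never reach the default score threshold anyway.
    """
    overlap = min(len(adapter), len(read_seq) - offset)
    if overlap <= 0:
        return False
    win = min(_SEED_LEN, overlap)
    mism = sum(
        1 for i in range(win) if read_seq[offset + i] != adapter[i]
    )
    if mism <= max_mismatch:
        return True
    for start in range(1, overlap - win + 1):
        if read_seq[offset + start - 1] != adapter[start - 1]:
            mism -= 1
        if read_seq[offset + start + win - 1] != adapter[start + win - 1]:
            mism += 1
        if mism <= max_mismatch:
            return True
    return False


def clip_adapter(
    read: QualRead, adapters: Sequence[str], params: TrimParams = TrimParams()
) -> QualRead:
    """Truncate a read at the start of the best-scoring adapter alignment.

    An alignment qualifies when it is seeded (a 16-mer of the overlap with
    at most ``adapter_seed_mismatches`` mismatches) and its local-alignment
    score reaches ``simple_threshold``. Among qualifying alignments the
    highest score wins; ties resolve to the smallest offset (longest clip).
    """
    if not adapters:
        raise ValueError("adapters must be non-empty")
    for a in adapters:
        if not a:
            raise ValueError("empty adapter sequence")
    best_score = None
    best_offset = None
    for adapter in adapters:
        for offset in range(len(read.sequence)):
            if not _has_seed(read.sequence, adapter, offset, params.adapter_seed_mismatches):
                continue
            score, _ = _overlap_score(read.sequence, adapter, offset)
            if score >= params.simple_threshold:
                if (
                    best_score is None
                    or score > best_score
                    or (score == best_score and offset < best_offset)
                ):
                    best_score = score
                    best_offset = offset
    if best_offset is None:
        return read
    return read.prefix(best_offset)


def _id_stem(read_id: str) -> str:
    stem = read_id.split()[0] if read_id else read_id
    if len(stem) > 2 and stem[-2] == "/" and stem[-1] in "12":
        stem = stem[:-2]
    return stem


def filter_pairs(
    pairs: Iterable[tuple[QualRead, QualRead]], min_len: int
) -> tuple[list[tuple[QualRead, QualRead]], TrimStats]:
    """Keep a pair only if both mates are at least ``min_len`` after trimming.

    Pairs with a single surviving read are dropped outright (the orphan
    rule); mate identifiers must agree on their stem.
    """
    stats = TrimStats()
    kept: list[tuple[QualRead, QualRead]] = []
    for r1, r2 in pairs:
        if _id_stem(r1.id) != _id_stem(r2.id):
            raise FastqFormatError(
                f"unsynchronized mates: {r1.id!r} vs {r2.id!r}"
            )
        stats.pairs_in += 1
        if len(r1) >= min_len and len(r2) >= min_len:
            kept.append((r1, r2))
            stats.pairs_out += 1
        else:
            stats.pairs_dropped += 1
    return kept, stats


def trim_pairs(
    pairs: Iterable[tuple[QualRead, QualRead]],
    adapters: Sequence[str] | None,
    params: TrimParams = TrimParams(),
) -> tuple[list[tuple[QualRead, QualRead]], TrimStats]:
    """Full per-pair pipeline: adapter clip -> window trim -> length/orphan filter."""
    stats = TrimStats()
    trimmed: list[tuple[QualRead, QualRead]] = []
    for r1, r2 in pairs:
        if _id_stem(r1.id) != _id_stem(r2.id):
            raise FastqFormatError(f"unsynchronized mates: {r1.id!r} vs {r2.id!r}")
        stats.pairs_in += 1
        out_pair = []
        for read in (r1, r2):
            stats.bases_in += len(read)
            if adapters:
                clipped = clip_adapter(read, adapters, params)
                if len(clipped) < len(read):
                    stats.reads_adapter_clipped += 1
                read = clipped
            windowed = sliding_window_trim(read, params)
            if len(windowed) < len(read):
                stats.reads_quality_trimmed += 1
            out_pair.append(windowed)
        r1t, r2t = out_pair
        if len(r1t) >= params.min_len and len(r2t) >= params.min_len:
            trimmed.append((r1t, r2t))
            stats.pairs_out += 1
            stats.bases_out += len(r1t) + len(r2t)
        else:
            stats.pairs_dropped += 1
    return trimmed, stats


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, mate: int = 1) -> Iterator[QualRead]:
    """Parse Phred+33 FASTQ (plain or gzip).

    A quality line whose characters all sit at or above ';' (Phred+64 '@'
    region with no character below Q26 in +33 terms) while containing
    characters above 'J' is taken as Phred+64 and rejected.
    """
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FastqFormatError(f"{path}: malformed FASTQ record near {header!r}")
            if qual and min(qual) >= "K" and max(qual) > "J":
                raise FastqFormatError(
                    f"{path}: qualities look Phred+64 encoded; only Phred+33 is supported"
                )
            yield QualRead(
                id=header[1:],
                sequence=seq,
                qualities=tuple(ord(c) - 33 for c in qual),
                mate=mate,
            )


def write_fastq(reads: Iterable[QualRead], path: str | Path) -> int:
    n = 0
    with _open_maybe_gzip(path, "wt") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n")
            fh.write("".join(chr(q + 33) for q in read.qualities) + "\n")
            n += 1
    return n


def trim_files(
    r1_path: str | Path,
    r2_path: str | Path,
    out_prefix: str | Path,
    adapters: Sequence[str] | None = None,
    params: TrimParams = TrimParams(),
) -> TrimStats:
    """Trim a two-file paired layout, writing <prefix>_1.fastq / _2.fastq + stats JSON."""
    reads1 = list(read_fastq(r1_path, mate=1))
    reads2 = list(read_fastq(r2_path, mate=2))
    if len(reads1) != len(reads2):
        raise FastqFormatError(
            f"mate files differ in record count: {len(reads1)} vs {len(reads2)}"
        )
    kept, stats = trim_pairs(zip(reads1, reads2), adapters, params)
    out_prefix = Path(out_prefix)
    write_fastq((p[0] for p in kept), f"{out_prefix}_1.fastq")
    write_fastq((p[1] for p in kept), f"{out_prefix}_2.fastq")
    with open(f"{out_prefix}_trim_stats.json", "w") as fh:
        json.dump(stats.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return stats
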