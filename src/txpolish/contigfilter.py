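"""Post-assembly contig cleanup: adapter clipping, contamination triage, length filter.

Three procedures applied in order to a freshly assembled transcriptome:

1. **Adapter scan/clip** — residual adapter fragments inside contigs are
   located by seed-and-extend (shared 4-mers extended ungapped, match +1 /
   mismatch -2) and judged significant by a Karlin-Altschul e-value
   ``K * m * n * exp(-lambda * S) <= 0.01``. Adapter spans are excised; the
   longest surviving segment replaces the contig, which is discarded if
   that segment falls below the 200-nt report cutoff.

2. **Contamination triage** — a contig with a hit against the related
   reference genome passing all of (e-value < 1e-5, alignment length > 100,
   identity > 80%) is accepted as a true plant contig. Otherwise its best
   hit in the general nucleotide database decides: a bacterial best hit
   removes the contig; a non-bacterial best hit keeps it; no hit at all
   keeps it.

3. **Length filter** — sequences shorter than 400 nt are removed from the
   final assembly (a 400-nt sequence survives).

Every removal is recorded with its reason in a :class:`CleanupReport`
whose per-stage counts reconcile exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from txpolish.hits import HitRecord

__all__ = [
    "Contig",
    "TriageLabel",
    "Triage",
    "TriageThresholds",
    "AdapterScanParams",
    "CleanupReport",
    "scan_adapters",
    "clip_contig",
    "classify_contamination",
    "length_filter",
    "run_cleanup",
    "read_taxonomy",
]

BACTERIAL_GROUP = "Bacteria"


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


class TriageLabel(str, Enum):
    PLANT_REFERENCE = "PLANT_REFERENCE"
    NO_HIT_KEPT = "NO_HIT_KEPT"
    NONBACTERIAL_KEPT = "NONBACTERIAL_KEPT"
    BACTERIAL_REMOVED = "BACTERIAL_REMOVED"

    @property
    def removed(self) -> bool:
        return self is TriageLabel.BACTERIAL_REMOVED


@dataclass(frozen=True)
class Triage:
    """Triage outcome for one contig, with the supporting hit when one exists."""

    contig_id: str
    label: TriageLabel
    evidence: HitRecord | None = None


@dataclass(frozen=True)
class TriageThresholds:
    """Stage-1 reference-hit acceptance thresholds (all must hold)."""

    evalue: float = 1e-5
    aln_length: int = 100
    pct_identity: float = 80.0


@dataclass(frozen=True)
class AdapterScanParams:
    word_size: int = 4
    evalue_max: float = 0.01
    match: int = 1
    mismatch: int = -2
    lam: float = 1.28
    karlin_k: float = 0.46
    xdrop: int = 20

    def __post_init__(self) -> None:
        if self.word_size < 2:
            raise ValueError("word_size must be >= 2")


class TaxonomyError(KeyError):
    """A hit subject is missing from the taxonomy map — never silently kept."""


def _extend_diagonal(
    contig: str, adapter: str, cpos: int, apos: int, params: AdapterScanParams
) -> tuple[int, int, int]:
    """Maximal-scoring ungapped extension of a seed word along its diagonal.

    Returns (contig_start, contig_end, score) as a 0-based half-open span on
    the contig. Extension proceeds base by base in each direction, keeping
    the best running score; it stops when the running score drops ``xdrop``
    below the best seen.
    """
    w = params.word_size
    score = w * params.match  # the exact seed word

    best_right = 0
    run = 0
    gain_right = 0
    i, j = cpos + w, apos + w
    while i < len(contig) and j < len(adapter):
        run += params.match if contig[i] == adapter[j] else params.mismatch
        if run > gain_right:
            gain_right = run
            best_right = i - (cpos + w) + 1
        if run < gain_right - params.xdrop:
            break
        i += 1
        j += 1

    best_left = 0
    run = 0
    gain_left = 0
    i, j = cpos - 1, apos - 1
    while i >= 0 and j >= 0:
        run += params.match if contig[i] == adapter[j] else params.mismatch
        if run > gain_left:
            gain_left = run
            best_left = cpos - i
        if run < gain_left - params.xdrop:
            break
        i -= 1
        j -= 1

    return cpos - best_left, cpos + w + best_right, score + gain_left + gain_right


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [spans[0]]
    for start, end in spans[1:]:
        if start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def scan_adapters(
    contig: Contig | str,
    adapters: Sequence[str],
    params: AdapterScanParams = AdapterScanParams(),
) -> list[tuple[int, int]]:
    """Locate adapter-derived spans on a contig (0-based half-open, merged).

    Every exact ``word_size``-mer shared between an adapter and the contig
    seeds an ungapped extension; the extension's span is reported when its
    Karlin-Altschul e-value ``K*m*n*exp(-lambda*S)`` is at most
    ``evalue_max``. Overlapping reported spans are merged.
    """
    if not adapters:
        raise ValueError("adapters must be non-empty")
    seq = contig.sequence if isinstance(contig, Contig) else contig
    w = params.word_size
    n = len(seq)
    contig_words: dict[str, list[int]] = {}
    for i in range(n - w + 1):
        contig_words.setdefault(seq[i : i + w], []).append(i)

    spans: list[tuple[int, int]] = []
    for adapter in adapters:
        m = len(adapter)
        seen_diagonals: set[int] = set()
        for apos in range(m - w + 1):
            word = adapter[apos : apos + w]
            for cpos in contig_words.get(word, ()):
                diag = cpos - apos
                if diag in seen_diagonals:
                    continue
                seen_diagonals.add(diag)
                start, end, score = _extend_diagonal(seq, adapter, cpos, apos, params)
                evalue = params.karlin_k * m * n * math.exp(-params.lam * score)
                if evalue <= params.evalue_max:
                    spans.append((start, end))
    return _merge_spans(spans)


def clip_contig(
    contig: Contig, spans: Sequence[tuple[int, int]], min_len: int = 200
) -> Contig | None:
    """Excise adapter spans, keep the longest remaining segment.

    Returns the clipped contig (id preserved) or ``None`` when the longest
    surviving segment is shorter than ``min_len``.
    """
    if not spans:
        return contig
    n = len(contig.sequence)
    merged = _merge_spans(list(spans))
    for start, end in merged:
        if start < 0 or end > n or start >= end:
            raise ValueError(
                f"contig {contig.id}: span [{start},{end}) out of bounds for length {n}"
            )
    segments: list[tuple[int, int]] = []
    prev = 0
    for start, end in merged:
        if start > prev:
            segments.append((prev, start))
        prev = end
    if prev < n:
        segments.append((prev, n))
    if not segments:
        return None
    best = max(segments, key=lambda s: (s[1] - s[0], -s[0]))
    if best[1] - best[0] < min_len:
        return None
    return Contig(id=contig.id, sequence=contig.sequence[best[0] : best[1]])


def _passes_reference(hit: HitRecord, thresholds: TriageThresholds) -> bool:
    return (
        hit.evalue < thresholds.evalue
        and hit.length > thresholds.aln_length
        and hit.pident > thresholds.pct_identity
    )


def _best_hit(hits: Sequence[HitRecord]) -> HitRecord:
    """Best hit: max bitscore, ties by min e-value, then max aligned length, then subject id."""
    return min(
        hits, key=lambda h: (-h.bitscore, h.evalue, -h.length, h.sseqid)
    )


def classify_contamination(
    contig_id: str,
    ref_hits: Sequence[HitRecord],
    nt_hits: Sequence[HitRecord],
    taxonomy: Mapping[str, str],
    thresholds: TriageThresholds = TriageThresholds(),
) -> Triage:
    """Two-stage triage of one contig against reference-genome and nt hit sets."""
    for hit in ref_hits:
        if _passes_reference(hit, thresholds):
            return Triage(contig_id, TriageLabel.PLANT_REFERENCE, hit)
    if not nt_hits:
        return Triage(contig_id, TriageLabel.NO_HIT_KEPT, None)
    best = _best_hit(list(nt_hits))
    if best.sseqid not in taxonomy:
        raise TaxonomyError(
            f"contig {contig_id}: subject {best.sseqid!r} missing from taxonomy map"
        )
    if taxonomy[best.sseqid] == BACTERIAL_GROUP:
        return Triage(contig_id, TriageLabel.BACTERIAL_REMOVED, best)
    return Triage(contig_id, TriageLabel.NONBACTERIAL_KEPT, best)


def length_filter(
    contigs: Sequence[Contig], min_len: int = 400
) -> tuple[list[Contig], int]:
    """Remove sequences shorter than ``min_len``; a contig of exactly ``min_len`` survives."""
    survivors = [c for c in contigs if len(c) >= min_len]
    return survivors, len(contigs) - len(survivors)


@dataclass
class CleanupReport:
    """Per-stage survivor counts and per-contig removal reasons."""

    input_count: int = 0
    after_clip: int = 0
    after_triage: int = 0
    after_length: int = 0
    removed_adapter_clip: int = 0
    removed_bacterial: int = 0
    removed_short: int = 0
    clipped_contigs: list[str] = field(default_factory=list)
    removal_reasons: dict[str, str] = field(default_factory=dict)
    triage_labels: dict[str, str] = field(default_factory=dict)

    def check_conservation(self) -> None:
        """Stage outputs must equal inputs minus removals at every stage."""
        assert self.after_clip == self.input_count - self.removed_adapter_clip
        assert self.after_triage == self.after_clip - self.removed_bacterial
        assert self.after_length == self.after_triage - self.removed_short

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "after_adapter_clip": self.after_clip,
            "after_contamination_triage": self.after_triage,
            "after_length_filter": self.after_length,
            "removed": {
                "adapter_clip_below_min": self.removed_adapter_clip,
                "bacterial_best_hit": self.removed_bacterial,
                "below_final_length": self.removed_short,
            },
            "clipped_contigs": sorted(self.clipped_contigs),
            "removal_reasons": dict(sorted(self.removal_reasons.items())),
            "triage_labels": dict(sorted(self.triage_labels.items())),
        }


def _hits_by_query(df: pd.DataFrame) -> dict[str, list[HitRecord]]:
    by_query: dict[str, list[HitRecord]] = {}
    for _, row in df.iterrows():
        rec = HitRecord(**{c: row[c] for c in df.columns})
        by_query.setdefault(rec.qseqid, []).append(rec)
    return by_query


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Two-column TSV: subject_id <tab> taxon group."""
    taxonomy: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            subject, group = line.split("\t")[:2]
            taxonomy[subject] = group
    return taxonomy


def run_cleanup(
    contigs: Sequence[Contig],
    adapters: Sequence[str],
    ref_hits: pd.DataFrame,
    nt_hits: pd.DataFrame,
    taxonomy: Mapping[str, str],
    thresholds: TriageThresholds = TriageThresholds(),
    scan_params: AdapterScanParams = AdapterScanParams(),
    clip_min_len: int = 200,
    final_min_len: int = 400,
) -> tuple[list[Contig], CleanupReport]:
    """Full cleanup: adapter clip -> contamination triage -> final length filter."""
    report = CleanupReport(input_count=len(contigs))
    ref_by_query = _hits_by_query(ref_hits)
    nt_by_query = _hits_by_query(nt_hits)

    clipped: list[Contig] = []
    for contig in contigs:
        spans = scan_adapters(contig, adapters, scan_params)
        result = clip_contig(contig, spans, min_len=clip_min_len)
        if result is None:
            report.removed_adapter_clip += 1
            report.removal_reasons[contig.id] = "ADAPTER_CLIP_BELOW_MIN"
        else:
            if spans:
                report.clipped_contigs.append(contig.id)
            clipped.append(result)
    report.after_clip = len(clipped)

    survivors: list[Contig] = []
    for contig in clipped:
        triage = classify_contamination(
            contig.id,
            ref_by_query.get(contig.id, []),
            nt_by_query.get(contig.id, []),
            taxonomy,
            thresholds,
        )
        report.triage_labels[contig.id] = triage.label.value
        if triage.label.removed:
            report.removed_bacterial += 1
            report.removal_reasons[contig.id] = "BACTERIAL_BEST_HIT"
        else:
            survivors.append(contig)
    report.after_triage = len(survivors)

    final, n_short = length_filter(survivors, min_len=final_min_len)
    for contig in survivors:
        if len(contig) < final_min_len:
            report.removal_reasons[contig.id] = "BELOW_FINAL_LENGTH"
    report.removed_short = n_short
    report.after_length = len(final)
    report.check_conservation()
    return final, report


def write_report(report: CleanupReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
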