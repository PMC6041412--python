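"""Six-frame ORF enumeration and representative peptide selection.

For each contig, all six reading frames are scanned; every maximal
stop-to-stop open segment yields (a) the longest Met-initiated ORF within
it and (b) the full open segment as a 5'-partial candidate. Candidate sets
from external predictors can be merged in by coordinate identity.

The representative peptide per contig is the longest Met-initiated
candidate, unless similarity to a curated protein database (Swiss-Prot
style hit table) points toward another candidate — in which case the
candidate with the best alignment bitscore wins. A representative is kept
in the final peptide set only if it is longer than 100 amino acids or has
a significant database hit (e-value < 1e-10).

CDS coordinates are reported 1-based inclusive on the forward strand and
include the stop codon when one terminates the ORF, matching common
predictor output conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "OrfCandidate",
    "SwissProtHit",
    "RepresentativePeptide",
    "SelectionReason",
    "KeepReason",
    "translate",
    "revcomp",
    "find_orfs",
    "merge_candidates",
    "select_representative",
    "write_outputs",
]

_VALID = set("ACGTN")


class SequenceFormatError(ValueError):
    pass


class SelectionReason(str, Enum):
    LONGEST_MET = "LONGEST_MET"
    HIT_SCORE = "HIT_SCORE"


class KeepReason(str, Enum):
    LENGTH_GT_100 = "LENGTH_GT_100"
    HIT_E_LT_1e10 = "HIT_E_LT_1e10"
    NOT_KEPT = "NOT_KEPT"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(dna: str, frame: int = 1, strand: str = "+") -> str:
    """Standard-code translation of a framed sequence; stops rendered as '*'.

    Codons containing N translate to X unless the ambiguity is synonymous.
    For the minus strand the sequence is reverse-complemented first.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1..3, got {frame}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand}")
    dna = dna.upper()
    bad = set(dna) - _VALID
    if bad:
        raise SequenceFormatError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    working = revcomp(dna) if strand == "-" else dna
    framed = working[frame - 1 :]
    framed = framed[: len(framed) - len(framed) % 3]
    if not framed:
        return ""
    return str(Seq(framed).translate())


@dataclass(frozen=True)
class OrfCandidate:
    """A candidate coding region on a contig.

    ``cds_start``/``cds_end`` are 1-based inclusive forward-strand
    coordinates and include the terminating stop codon when present.
    """

    contig_id: str
    strand: str
    frame: int
    cds_start: int
    cds_end: int
    peptide: str
    met_initiated: bool
    has_stop: bool = True
    sources: tuple[str, ...] = ("internal",)

    def __post_init__(self) -> None:
        span = self.cds_end - self.cds_start + 1
        if span % 3 != 0:
            raise ValueError(
                f"{self.contig_id}: CDS span {self.cds_start}..{self.cds_end} "
                "not divisible by 3"
            )
        expected = span // 3 - (1 if self.has_stop else 0)
        if len(self.peptide) != expected:
            raise ValueError(
                f"{self.contig_id}: peptide length {len(self.peptide)} != codon "
                f"count {expected} for span {self.cds_start}..{self.cds_end}"
            )

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.contig_id, self.strand, self.cds_start, self.cds_end)

    @property
    def aa_length(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class SwissProtHit:
    """Best curated-database hit for one peptide candidate."""

    candidate_key: tuple[str, str, int, int]
    subject: str
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("negative e-value")


@dataclass(frozen=True)
class RepresentativePeptide:
    contig_id: str
    candidate: OrfCandidate
    selection_reason: SelectionReason
    kept: bool
    keep_reason: KeepReason

    def __post_init__(self) -> None:
        if self.kept and self.keep_reason is KeepReason.NOT_KEPT:
            raise ValueError("kept representative cannot have NOT_KEPT reason")


def _forward_coords(ws_start: int, ws_end: int, strand: str, contig_len: int) -> tuple[int, int]:
    """Map a 0-based half-open interval on the working (strand-oriented)
    sequence to 1-based inclusive forward-strand coordinates."""
    if strand == "+":
        return ws_start + 1, ws_end
    return contig_len - ws_end + 1, contig_len - ws_start


def find_orfs(contig_id: str, sequence: str, min_aa: int = 30) -> list[OrfCandidate]:
    """Enumerate ORF candidates in all six frames of a contig.

    Each maximal stop-to-stop segment contributes the longest Met-initiated
    ORF it contains, plus the full open segment as a 5'-partial candidate
    when the segment does not itself start with Met. Candidates shorter
    than ``min_aa`` amino acids are dropped.
    """
    sequence = sequence.upper()
    if len(sequence) < 3:
        return []
    n = len(sequence)
    candidates: list[OrfCandidate] = []
    for strand in ("+", "-"):
        working = revcomp(sequence) if strand == "-" else sequence
        for frame in (1, 2, 3):
            framed_len = (n - (frame - 1)) // 3 * 3
            if framed_len < 3:
                continue
            peptide = translate(working, frame=frame, strand="+")
            # split into stop-delimited segments, tracking codon offsets
            seg_start = 0
            for pos in range(len(peptide) + 1):
                at_stop = pos < len(peptide) and peptide[pos] == "*"
                at_end = pos == len(peptide)
                if not (at_stop or at_end):
                    continue
                seg = peptide[seg_start:pos]
                if seg:
                    has_stop = at_stop
                    ws_a = (frame - 1) + seg_start * 3
                    ws_b = (frame - 1) + (pos + (1 if has_stop else 0)) * 3
                    start_fwd, end_fwd = _forward_coords(ws_a, ws_b, strand, n)
                    met_idx = seg.find("M")
                    if met_idx == 0:
                        if len(seg) >= min_aa:
                            candidates.append(
                                OrfCandidate(
                                    contig_id, strand, frame, start_fwd, end_fwd,
                                    seg, met_initiated=True, has_stop=has_stop,
                                )
                            )
                    else:
                        if len(seg) >= min_aa:
                            candidates.append(
                                OrfCandidate(
                                    contig_id, strand, frame, start_fwd, end_fwd,
                                    seg, met_initiated=False, has_stop=has_stop,
                                )
                            )
                        if met_idx > 0:
                            met_pep = seg[met_idx:]
                            if len(met_pep) >= min_aa:
                                ws_m = (frame - 1) + (seg_start + met_idx) * 3
                                ms, me = _forward_coords(ws_m, ws_b, strand, n)
                                candidates.append(
                                    OrfCandidate(
                                        contig_id, strand, frame, ms, me,
                                        met_pep, met_initiated=True, has_stop=has_stop,
                                    )
                                )
                seg_start = pos + 1
    return candidates


def merge_candidates(
    internal: Sequence[OrfCandidate], *external_sets: Sequence[OrfCandidate]
) -> list[OrfCandidate]:
    """Deduplicate candidates by (contig, strand, start, end), merging sources."""
    merged: dict[tuple, OrfCandidate] = {}
    for cand_set in (internal, *external_sets):
        for cand in cand_set:
            if cand.key in merged:
                prior = merged[cand.key]
                sources = tuple(dict.fromkeys(prior.sources + cand.sources))
                merged[cand.key] = replace(prior, sources=sources)
            else:
                merged[cand.key] = cand
    return sorted(merged.values(), key=lambda c: c.key)


def select_representative(
    candidates: Sequence[OrfCandidate],
    hits: Mapping[tuple, SwissProtHit] | Sequence[SwissProtHit] = (),
    evalue_keep: float = 1e-10,
    min_keep_aa: int = 100,
) -> RepresentativePeptide:
    """Choose the representative peptide for one contig and apply the keep rule.

    With at least one candidate carrying a significant database hit
    (e-value < ``evalue_keep``) the winner is the candidate with the best
    bitscore (ties: longer peptide, then lower cds_start). Otherwise the
    longest Met-initiated candidate wins (ties: lower cds_start); if none
    is Met-initiated the longest candidate wins. A winner is kept if its
    peptide exceeds ``min_keep_aa`` amino acids or it carries a significant
    hit.
    """
    if not candidates:
        raise ValueError("cannot select a representative from zero candidates")
    contig_ids = {c.contig_id for c in candidates}
    if len(contig_ids) != 1:
        raise ValueError(f"candidates span multiple contigs: {sorted(contig_ids)}")
    contig_id = candidates[0].contig_id

    if not isinstance(hits, Mapping):
        hit_map: dict[tuple, SwissProtHit] = {}
        for hit in hits:
            prior = hit_map.get(hit.candidate_key)
            if prior is None or hit.bitscore > prior.bitscore:
                hit_map[hit.candidate_key] = hit
    else:
        hit_map = dict(hits)

    significant = [
        c for c in candidates
        if c.key in hit_map and hit_map[c.key].evalue < evalue_keep
    ]
    if significant:
        winner = min(
            significant,
            key=lambda c: (-hit_map[c.key].bitscore, -c.aa_length, c.cds_start),
        )
        reason = SelectionReason.HIT_SCORE
    else:
        met = [c for c in candidates if c.met_initiated]
        pool = met if met else list(candidates)
        winner = min(pool, key=lambda c: (-c.aa_length, c.cds_start))
        reason = SelectionReason.LONGEST_MET

    has_sig_hit = (
        winner.key in hit_map and hit_map[winner.key].evalue < evalue_keep
    )
    if winner.aa_length > min_keep_aa:
        kept, keep_reason = True, KeepReason.LENGTH_GT_100
    elif has_sig_hit:
        kept, keep_reason = True, KeepReason.HIT_E_LT_1e10
    else:
        kept, keep_reason = False, KeepReason.NOT_KEPT
    return RepresentativePeptide(contig_id, winner, reason, kept, keep_reason)


def write_outputs(
    representatives: Sequence[RepresentativePeptide],
    peptide_fasta: str | Path,
    cds_gff3: str | Path,
    report_tsv: str | Path | None = None,
    kept_only: bool = True,
) -> None:
    """Write peptide FASTA + CDS GFF3 (+ optional selection-report TSV).

    GFF3 records carry type CDS, 1-based inclusive coordinates including
    the stop codon, phase 0, and ID=<contig>.p1 matching the FASTA ids.
    """
    emitted = [r for r in representatives if r.kept] if kept_only else list(representatives)
    with open(peptide_fasta, "w") as fa:
        for rep in emitted:
            fa.write(f">{rep.contig_id}.p1\n{rep.candidate.peptide}\n")
    with open(cds_gff3, "w") as gff:
        gff.write("##gff-version 3\n")
        gff.write("# CDS coordinates include the terminating stop codon when present\n")
        for rep in emitted:
            c = rep.candidate
            gff.write(
                "\t".join(
                    [
                        c.contig_id,
                        "txpolish",
                        "CDS",
                        str(c.cds_start),
                        str(c.cds_end),
                        ".",
                        c.strand,
                        "0",
                        f"ID={c.contig_id}.p1",
                    ]
                )
                + "\n"
            )
    if report_tsv is not None:
        with open(report_tsv, "w") as tsv:
            tsv.write("contig\tselection_reason\tkept\tkeep_reason\tpeptide_length\n")
            for rep in representatives:
                tsv.write(
                    f"{rep.contig_id}\t{rep.selection_reason.value}\t"
                    f"{str(rep.kept).lower()}\t{rep.keep_reason.value}\t"
                    f"{rep.candidate.aa_length}\n"
                )
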