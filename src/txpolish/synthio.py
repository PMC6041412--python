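"""Seeded synthetic fixtures with ground truth for every pipeline stage.

The generator stands in for the deposited sequencing libraries and
assembly: it produces contigs with planted adapter fragments, a mixture of
plant-like and bacterial-like contigs backed by consistent hit tables and
a taxonomy map, contigs carrying a single known CDS, paired FASTQ reads
with independently computed true trim points, and count matrices with
designed tissue-exclusive subsets. Every planted feature is recorded in a
manifest so downstream stages can be verified round-trip at desk scale.

All randomness flows through a numpy generator seeded per call: the same
seed and parameters give byte-identical artifacts. Truth intervals are
stored 0-based half-open; conversion to 1-based inclusive happens only at
GFF3 emission.

Bacterial-like contigs are resequenced at a distinct GC (default 0.65)
purely for realism; contamination triage relies on the hit tables, never
on composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from txpolish.contigfilter import Contig
from txpolish.expr import VennPartition
from txpolish.hits import HitRecord
from txpolish.readtrim import QualRead

__all__ = [
    "DEFAULT_ADAPTER",
    "FixtureManifest",
    "make_contigs",
    "plant_adapters",
    "plant_contaminants",
    "plant_orfs",
    "make_count_matrix",
    "make_read_pairs",
    "make_end_to_end",
    "write_fasta",
]

# Illumina TruSeq universal adapter (33 nt), the default planted sequence.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_BASES = np.array(list("ACGT"))

_CODONS = {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"], "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"], "K": ["AAA", "AAG"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "C": ["TGT", "TGC"], "W": ["TGG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"], "G": ["GGT", "GGC", "GGA", "GGG"],
}
_STOPS = ["TAA", "TAG", "TGA"]
_AA = sorted(_CODONS)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FixtureManifest:
    """Ground truth for one generated fixture set.

    ``records`` maps contig id to its truth entry (planted adapter spans as
    0-based half-open intervals, contamination label, true CDS span/strand,
    peptide). ``reads`` maps read-pair stems to true trim points and adapter
    positions; ``venn`` holds the designed region sizes.
    """

    seed: int
    records: dict[str, dict] = field(default_factory=dict)
    reads: dict[str, dict] = field(default_factory=dict)
    venn: dict[str, int] = field(default_factory=dict)

    def entry(self, contig_id: str) -> dict:
        return self.records.setdefault(contig_id, {})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "records": self.records,
            "reads": self.reads,
            "venn": self.venn,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            seed=payload["seed"],
            records=payload.get("records", {}),
            reads=payload.get("reads", {}),
            venn=payload.get("venn", {}),
        )


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def make_contigs(
    n: int,
    length_range: tuple[int, int] = (500, 3000),
    gc: float = 0.40,
    seed: int = 0,
    prefix: str = "contig",
) -> tuple[list[Contig], FixtureManifest]:
    """Random contigs with lengths uniform in ``length_range`` and the given GC."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    manifest = FixtureManifest(seed=seed)
    contigs = []
    width = len(str(n))
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        cid = f"{prefix}_{i:0{width}d}"
        contigs.append(Contig(cid, _random_seq(rng, length, gc)))
        manifest.entry(cid)["length"] = length
    return contigs, manifest


def plant_adapters(
    contigs: Sequence[Contig],
    adapter: str = DEFAULT_ADAPTER,
    rate: float = 0.1,
    seed: int = 0,
    manifest: FixtureManifest | None = None,
    spans_per_contig: int = 1,
    min_fragment_frac: float = 0.75,
) -> tuple[list[Contig], FixtureManifest]:
    """Overwrite adapter (or a >=75% fragment) into a fraction of contigs.

    Exactly ``round(rate * n)`` contigs are selected; each receives
    ``spans_per_contig`` non-overlapping planted spans, recorded 0-based
    half-open in the manifest.
    """
    if len(adapter) < 10:
        raise ValueError("adapter must be at least 10 nt")
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    shortest = min(len(c) for c in contigs)
    if len(adapter) > shortest:
        raise ValueError(
            f"adapter ({len(adapter)} nt) longer than shortest contig ({shortest} nt)"
        )
    rng = np.random.default_rng(seed)
    manifest = manifest or FixtureManifest(seed=seed)
    n_select = round(rate * len(contigs))
    selected = set(rng.permutation(len(contigs))[:n_select].tolist())
    out: list[Contig] = []
    min_frag = int(np.ceil(min_fragment_frac * len(adapter)))
    for idx, contig in enumerate(contigs):
        entry = manifest.entry(contig.id)
        entry.setdefault("adapter_spans", [])
        if idx not in selected:
            out.append(contig)
            continue
        seq = contig.sequence
        spans: list[tuple[int, int]] = []
        for _ in range(spans_per_contig):
            frag_len = int(rng.integers(min_frag, len(adapter) + 1))
            frag_start = int(rng.integers(0, len(adapter) - frag_len + 1))
            fragment = adapter[frag_start : frag_start + frag_len]
            for _attempt in range(200):
                pos = int(rng.integers(0, len(seq) - frag_len + 1))
                span = (pos, pos + frag_len)
                if all(span[1] + 50 <= s or e + 50 <= span[0] for s, e in spans):
                    break
            else:  # pragma: no cover - tiny contigs with many spans
                continue
            seq = seq[: span[0]] + fragment + seq[span[1] :]
            spans.append(span)
        spans.sort()
        entry["adapter_spans"] = [list(s) for s in spans]
        out.append(Contig(contig.id, seq))
    return out, manifest


def plant_contaminants(
    contigs: Sequence[Contig],
    bacterial_fraction: float = 0.2,
    seed: int = 0,
    no_hit_fraction: float = 0.1,
    nonbacterial_fraction: float = 0.0,
    gc_bacterial: float = 0.65,
    manifest: FixtureManifest | None = None,
) -> tuple[list[Contig], list[HitRecord], list[HitRecord], dict[str, str], FixtureManifest]:
    """Label contigs plant/bacterial/no-hit(/non-bacterial) and fabricate consistent hit tables.

    Plant contigs receive a reference-genome hit passing all three triage
    thresholds; bacterial contigs receive no passing reference hit but a
    best general-database hit mapping to a bacterial taxon (and are
    resequenced at ``gc_bacterial`` for realism); no-hit contigs appear in
    neither table; non-bacterial contaminants get a fungal best hit.
    Returns (contigs, ref_hits, nt_hits, taxonomy, manifest).
    """
    for frac in (bacterial_fraction, no_hit_fraction, nonbacterial_fraction):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must be in [0, 1]")
    if bacterial_fraction + no_hit_fraction + nonbacterial_fraction > 1:
        raise ValueError("label fractions sum to more than 1")
    rng = np.random.default_rng(seed)
    manifest = manifest or FixtureManifest(seed=seed)
    n = len(contigs)
    n_bact = round(bacterial_fraction * n)
    n_nohit = round(no_hit_fraction * n)
    n_nonbact = round(nonbacterial_fraction * n)
    order = rng.permutation(n)
    bact_idx = set(order[:n_bact].tolist())
    nohit_idx = set(order[n_bact : n_bact + n_nohit].tolist())
    nonbact_idx = set(order[n_bact + n_nohit : n_bact + n_nohit + n_nonbact].tolist())

    bacterial_subjects = [f"NC_BACT{i:03d}" for i in range(1, 9)]
    fungal_subjects = [f"NW_FUNG{i:03d}" for i in range(1, 5)]
    plant_nt_subjects = [f"XM_PLNT{i:03d}" for i in range(1, 5)]
    taxonomy = {s: "Bacteria" for s in bacterial_subjects}
    taxonomy.update({s: "Fungi" for s in fungal_subjects})
    taxonomy.update({s: "Viridiplantae" for s in plant_nt_subjects})

    ref_hits: list[HitRecord] = []
    nt_hits: list[HitRecord] = []
    out: list[Contig] = []

    def _hit(q, s, pident, length, evalue, bitscore):
        qstart = int(rng.integers(1, 50))
        return HitRecord(
            qseqid=q, sseqid=s, pident=round(pident, 2), length=length,
            mismatch=int(length * (100 - pident) / 100), gapopen=0,
            qstart=qstart, qend=qstart + length - 1,
            sstart=1, send=length, evalue=evalue, bitscore=round(bitscore, 1),
        )

    for idx, contig in enumerate(contigs):
        entry = manifest.entry(contig.id)
        if idx in bact_idx:
            entry["contamination"] = "BACTERIAL_REMOVED"
            contig = Contig(
                contig.id, _random_seq(rng, len(contig), gc_bacterial)
            )
            if rng.random() < 0.5:  # a failing reference hit for realism
                ref_hits.append(
                    _hit(contig.id, "JcChr1", 70 + rng.random() * 9,
                         int(rng.integers(40, 100)), 10 ** -rng.uniform(2, 4.5),
                         50 + rng.random() * 30)
                )
            best_bit = 150 + rng.random() * 200
            nt_hits.append(
                _hit(contig.id, bacterial_subjects[int(rng.integers(len(bacterial_subjects)))],
                     85 + rng.random() * 13, int(rng.integers(120, 400)),
                     10 ** -rng.uniform(20, 60), best_bit)
            )
            if rng.random() < 0.5:  # a weaker non-bacterial hit below the best
                nt_hits.append(
                    _hit(contig.id, plant_nt_subjects[int(rng.integers(len(plant_nt_subjects)))],
                         80 + rng.random() * 10, int(rng.integers(80, 200)),
                         10 ** -rng.uniform(5, 15), best_bit - 30 - rng.random() * 50)
                )
        elif idx in nohit_idx:
            entry["contamination"] = "NO_HIT_KEPT"
        elif idx in nonbact_idx:
            entry["contamination"] = "NONBACTERIAL_KEPT"
            nt_hits.append(
                _hit(contig.id, fungal_subjects[int(rng.integers(len(fungal_subjects)))],
                     82 + rng.random() * 15, int(rng.integers(120, 350)),
                     10 ** -rng.uniform(15, 40), 150 + rng.random() * 150)
            )
        else:
            entry["contamination"] = "PLANT_REFERENCE"
            ref_hits.append(
                _hit(contig.id, "JcChr1", 81 + rng.random() * 18,
                     int(rng.integers(101, 500)), 10 ** -rng.uniform(10, 60),
                     200 + rng.random() * 600)
            )
        out.append(contig)
    return out, ref_hits, nt_hits, taxonomy, manifest


def _encode_peptide(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        _CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in peptide
    )


def _brute_force_met_orfs(seq: str) -> list[tuple[int, int, str, int]]:
    """All Met-initiated ORFs in six frames, by direct ATG scan.

    Returns (fwd_start0, fwd_end0_exclusive, strand, peptide_codons); the
    end includes the stop codon when one terminates the ORF. Independent of
    the production enumerator: works by scanning forward from every ATG.
    """
    n = len(seq)
    found = []
    for strand in ("+", "-"):
        s = _revcomp(seq) if strand == "-" else seq
        for i in range(n - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i
            codons = 0
            stopped = False
            while j + 3 <= n:
                codon = s[j : j + 3]
                if codon in _STOPS:
                    stopped = True
                    break
                codons += 1
                j += 3
            end = j + 3 if stopped else j
            if strand == "+":
                found.append((i, end, strand, codons))
            else:
                found.append((n - end, n - i, strand, codons))
    return found


def plant_orfs(
    n: int,
    peptide_lengths: tuple[int, int] = (100, 300),
    strand_mix: float = 0.5,
    seed: int = 0,
    flank_range: tuple[int, int] = (60, 300),
    prefix: str = "orf",
    manifest: FixtureManifest | None = None,
) -> tuple[list[Contig], FixtureManifest]:
    """Contigs each carrying exactly one maximal Met-initiated, stop-terminated CDS.

    The planted CDS is verified at generation time, by a brute-force ATG
    scan over all six frames, to be strictly the longest Met-initiated ORF
    in the contig; contigs failing the check are resampled. Truth spans are
    recorded 0-based half-open on the forward strand, stop codon included,
    with strand and peptide.
    """
    if peptide_lengths[0] < 10:
        raise ValueError("minimum peptide length is 10 aa")
    if n < 1:
        raise ValueError("n must be >= 1")
    min_flank_needed = flank_range[1]
    if min_flank_needed < flank_range[0]:
        raise ValueError("invalid flank range")
    rng = np.random.default_rng(seed)
    manifest = manifest or FixtureManifest(seed=seed)
    n_minus = round(strand_mix * n)
    strands = ["-"] * n_minus + ["+"] * (n - n_minus)
    strands = [strands[i] for i in rng.permutation(n)]
    contigs: list[Contig] = []
    width = len(str(n))
    for i in range(n):
        strand = strands[i]
        for _attempt in range(500):
            pep_len = int(rng.integers(peptide_lengths[0], peptide_lengths[1] + 1))
            peptide = "M" + "".join(
                _AA[int(k)] for k in rng.integers(0, len(_AA), pep_len - 1)
            )
            cds = _encode_peptide(rng, peptide) + _STOPS[int(rng.integers(3))]
            insert = _revcomp(cds) if strand == "-" else cds
            left = _random_seq(rng, int(rng.integers(*flank_range)), 0.40)
            right = _random_seq(rng, int(rng.integers(*flank_range)), 0.40)
            seq = left + insert + right
            start0 = len(left)
            end0 = start0 + len(cds)
            planted_codons = pep_len  # codons before the stop
            ok = False
            for fs, fe, st, codons in _brute_force_met_orfs(seq):
                if (fs, fe, st) == (start0, end0, strand):
                    ok = True
                elif codons >= planted_codons:
                    ok = False
                    break
            if ok:
                break
        else:  # pragma: no cover - resampling virtually always succeeds
            raise RuntimeError("could not plant an unambiguous ORF")
        cid = f"{prefix}_{i:0{width}d}"
        entry = manifest.entry(cid)
        entry["cds_span"] = [start0, end0]
        entry["cds_strand"] = strand
        entry["peptide"] = peptide
        contigs.append(Contig(cid, seq))
    return contigs, manifest


def make_count_matrix(
    tissues: Sequence[str],
    n_transcripts: int,
    exclusive_design: Mapping[str, int],
    seed: int = 0,
    n_absent: int = 0,
    count_range: tuple[int, int] = (1, 500),
    transcript_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, VennPartition]:
    """Count matrix with designed tissue-exclusive subsets and a truth partition.

    The first ``exclusive_design[t]`` transcripts (after a seeded shuffle)
    are expressed only in tissue t; ``n_absent`` transcripts get all-zero
    rows; the remainder are expressed in every tissue. The returned truth
    partition is constructed from the design, not computed from the matrix.
    """
    tissues = list(tissues)
    if not tissues:
        raise ValueError("tissues must be non-empty")
    unknown = set(exclusive_design) - set(tissues)
    if unknown:
        raise ValueError(f"design names unknown tissues: {sorted(unknown)}")
    n_designed = sum(exclusive_design.values())
    if n_designed + n_absent > n_transcripts:
        raise ValueError("design exceeds transcript count")
    rng = np.random.default_rng(seed)
    if transcript_ids is None:
        width = len(str(n_transcripts))
        transcript_ids = [f"tx_{i:0{width}d}" for i in range(n_transcripts)]
    elif len(transcript_ids) != n_transcripts:
        raise ValueError("transcript_ids length mismatch")
    order = rng.permutation(n_transcripts)
    counts = np.zeros((n_transcripts, len(tissues)), dtype=int)
    truth = VennPartition(tissues=tuple(tissues))
    cursor = 0
    for tissue, n_excl in exclusive_design.items():
        col = tissues.index(tissue)
        for idx in order[cursor : cursor + n_excl]:
            counts[idx, col] = rng.integers(count_range[0], count_range[1] + 1)
        if n_excl:
            truth.regions[frozenset([tissue])] = n_excl
        cursor += n_excl
    cursor += n_absent  # all-zero rows
    truth.n_absent = n_absent
    shared = order[cursor:]
    for idx in shared:
        counts[idx, :] = rng.integers(count_range[0], count_range[1] + 1, len(tissues))
    if len(shared):
        truth.regions[frozenset(tissues)] = len(shared)
    df = pd.DataFrame(counts, index=list(transcript_ids), columns=tissues)
    df.index.name = "transcript"
    return df, truth


def _window_trim_oracle(quals: np.ndarray, window: int = 4, mean_q: float = 15.0) -> int:
    """Independent trim-point oracle: vectorised mean over every window start.

    Windows extend ``window`` bases or to the read end; returns the kept
    prefix length under the first-failing-window rule.
    """
    n = len(quals)
    if n == 0:
        return 0
    csum = np.concatenate([[0], np.cumsum(quals)])
    starts = np.arange(n)
    ends = np.minimum(starts + window, n)
    means = (csum[ends] - csum[starts]) / (ends - starts)
    failing = np.nonzero(means < mean_q)[0]
    return int(failing[0]) if len(failing) else n


def make_read_pairs(
    n_pairs: int,
    read_len: int = 150,
    quality_profile: tuple = ("step", 38, 2),
    adapter_rate: float = 0.0,
    seed: int = 0,
    adapter: str = DEFAULT_ADAPTER,
    window: int = 4,
    mean_q: float = 15.0,
    jitter: int = 2,
) -> tuple[list[QualRead], list[QualRead], FixtureManifest]:
    """Paired reads with per-read true trim points recorded in the manifest.

    ``quality_profile`` is ``("constant", q)`` or ``("step", q_high,
    q_low)``; the step breakpoint is drawn per mate, and qualities carry a
    small uniform jitter. True trim points are computed by an independent
    vectorised window-scan oracle on the final quality strings. A fraction
    ``adapter_rate`` of R1 reads have their 3' tail overwritten with the
    adapter, position recorded.
    """
    if read_len < 20:
        raise ValueError("read_len must be >= 20")
    rng = np.random.default_rng(seed)
    manifest = FixtureManifest(seed=seed)
    kind = quality_profile[0]
    reads1: list[QualRead] = []
    reads2: list[QualRead] = []
    n_adapter = round(adapter_rate * n_pairs)
    adapter_pairs = set(rng.permutation(n_pairs)[:n_adapter].tolist())
    width = len(str(max(n_pairs, 1)))
    for i in range(n_pairs):
        stem = f"read_{i:0{width}d}"
        truth: dict = {}
        pair = []
        for mate in (1, 2):
            if kind == "constant":
                quals = np.full(read_len, quality_profile[1], dtype=int)
            elif kind == "step":
                q_high, q_low = quality_profile[1], quality_profile[2]
                break_at = int(rng.integers(window, read_len + 1))
                quals = np.where(
                    np.arange(read_len) < break_at, q_high, q_low
                ).astype(int)
            else:
                raise ValueError(f"unknown quality profile {kind!r}")
            if jitter:
                quals = quals + rng.integers(-jitter, jitter + 1, read_len)
            quals = np.clip(quals, 0, 41)
            seq = "".join(rng.choice(_BASES, size=read_len))
            if mate == 1 and i in adapter_pairs:
                pos = int(rng.integers(read_len - len(adapter), read_len - 9))
                frag = adapter[: read_len - pos]
                seq = seq[:pos] + frag
                truth["adapter1"] = pos
            truth[f"trim{mate}"] = _window_trim_oracle(quals, window, mean_q)
            pair.append(
                QualRead(f"{stem}/{mate}", seq, tuple(int(q) for q in quals), mate)
            )
        manifest.reads[stem] = truth
        reads1.append(pair[0])
        reads2.append(pair[1])
    return reads1, reads2, manifest


def write_fasta(contigs: Sequence[Contig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.id}\n")
            for i in range(0, len(contig.sequence), width):
                fh.write(contig.sequence[i : i + width] + "\n")


TISSUES = ("leaf", "stem", "inflorescence", "seed", "root")


def make_end_to_end(
    outdir: str | Path,
    seed: int = 0,
    n_contigs: int = 60,
    n_pairs: int = 40,
    adapter_rate: float = 0.1,
    bacterial_fraction: float = 0.2,
    no_hit_fraction: float = 0.1,
    exclusive_design: Mapping[str, int] | None = None,
) -> FixtureManifest:
    """Write a complete pipeline input set under ``outdir``.

    Produces paired FASTQ, adapters FASTA, an assembly of CDS-bearing
    contigs with planted adapters and contaminants, the two hit tables and
    taxonomy map for triage, forward/reverse peptide-vs-reference hit
    tables with a functional table for RBH annotation, a per-tissue count
    matrix, and the consolidated truth manifest (manifest.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, 8)]

    r1, r2, read_manifest = make_read_pairs(
        n_pairs, adapter_rate=adapter_rate, seed=sub[0]
    )
    from txpolish.readtrim import write_fastq

    write_fastq(r1, outdir / "reads_1.fastq")
    write_fastq(r2, outdir / "reads_2.fastq")
    with open(outdir / "adapters.fa", "w") as fh:
        fh.write(f">truseq_universal\n{DEFAULT_ADAPTER}\n")

    contigs, manifest = plant_orfs(n_contigs, seed=sub[1], prefix="contig")
    manifest.reads = read_manifest.reads
    contigs, ref_hits, nt_hits, taxonomy, manifest = plant_contaminants(
        contigs,
        bacterial_fraction=bacterial_fraction,
        no_hit_fraction=no_hit_fraction,
        seed=sub[2],
        manifest=manifest,
    )
    contigs, manifest = plant_adapters(
        contigs, rate=adapter_rate, seed=sub[3], manifest=manifest
    )
    write_fasta(contigs, outdir / "contigs.fa")
    from txpolish.hits import write_hit_table

    write_hit_table(ref_hits, outdir / "ref_hits.tsv")
    write_hit_table(nt_hits, outdir / "nt_hits.tsv")
    with open(outdir / "taxonomy.tsv", "w") as fh:
        for subject in sorted(taxonomy):
            fh.write(f"{subject}\t{taxonomy[subject]}\n")

    # forward/reverse peptide-vs-reference tables consistent with planted CDSs:
    # each plant contig's representative peptide <id>.p1 pairs with one
    # reference gene; reciprocity holds by construction.
    fwd_rows, rev_rows, functions = [], [], {}
    gene_no = 0
    for contig in contigs:
        entry = manifest.records[contig.id]
        if entry.get("contamination") != "PLANT_REFERENCE":
            continue
        gene_no += 1
        pep = f"{contig.id}.p1"
        gene = f"AT{gene_no % 5 + 1}G{gene_no:05d}"
        bit = round(150 + float(rng.random()) * 400, 1)
        ev = 10.0 ** -float(rng.uniform(20, 80))
        plen = len(entry["peptide"])
        hit = HitRecord(pep, gene, round(60 + float(rng.random()) * 39, 2), plen,
                        0, 0, 1, plen, 1, plen, ev, bit)
        fwd_rows.append(hit)
        rev_rows.append(HitRecord(gene, pep, hit.pident, plen, 0, 0, 1, plen,
                                  1, plen, ev, bit))
        functions[gene] = f"synthetic reference protein {gene_no}"
        entry["rbh_gene"] = gene
    write_hit_table(fwd_rows, outdir / "pep_vs_ref.tsv")
    write_hit_table(rev_rows, outdir / "ref_vs_pep.tsv")
    with open(outdir / "ref_functions.tsv", "w") as fh:
        fh.write("gene\tdescription\n")
        for gene in sorted(functions):
            fh.write(f"{gene}\t{functions[gene]}\n")

    if exclusive_design is None:
        # tissue-exclusive fractions echo the study's pattern: root richest,
        # stem poorest
        fractions = {"root": 0.10, "leaf": 0.05, "seed": 0.034,
                     "inflorescence": 0.034, "stem": 0.033}
        exclusive_design = {
            t: max(1, round(f * n_contigs)) for t, f in fractions.items()
        }
    counts, truth = make_count_matrix(
        TISSUES,
        n_transcripts=n_contigs,
        exclusive_design=exclusive_design,
        seed=sub[4],
        transcript_ids=[c.id for c in contigs],
    )
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    manifest.venn = {
        "+".join(t for t in TISSUES if t in subset): count
        for subset, count in truth.regions.items()
    }
    manifest.to_json(outdir / "manifest.json")
    return manifest
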