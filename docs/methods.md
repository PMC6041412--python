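# Methods

This note documents the rules each stage implements, the tunable
parameters and their defaults, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the protocol left
room.

## Read trimming (`txpolish.readtrim`)

Reads are processed adapter clip → sliding-window trim → length/orphan
filter, the conventional order of read trimmers.

*Sliding window.* Scanning 5'→3', the read is truncated at the start
index of the first window whose **mean** Phred score is strictly below
the threshold (window 4, threshold Q15 by default). Windows at the 3' end
shorter than the window length — including reads shorter than the window
— are evaluated as windows of their own length. Whether a trailing
sub-window should be evaluated at all is a genuinely open choice; we
evaluate it, which can only trim more conservatively-scored tails, and
the synthetic truth oracle applies the identical rule.

*Adapter clipping.* Simple-mode seeded local alignment: an adapter
aligned at a read offset qualifies if some 16-mer of the overlap has at
most 2 mismatches (`adapter_seed_mismatches`) and the ungapped alignment
score (match +0.6, mismatch −3.0, no gaps) reaches the simple threshold
10. The read is truncated at the start of the best-scoring qualifying
alignment. Palindrome mode is **not** implemented; the
`palindrome_threshold` (30) is retained in the parameter block for
interface fidelity but unused — a documented limitation. With these
scores a qualifying match needs ≥ 17 matching bases, so overlaps shorter
than the 16-mer seed can never clip.

*Pair filter.* A pair survives only if both mates are ≥ 100 nt
(`min_len`) after trimming; single-survivor pairs are dropped, keeping
mate files synchronized. Only Phred+33 input is accepted; quality strings
that decode as Phred+64 raise a format error rather than mis-trim.

## Contig cleanup (`txpolish.contigfilter`)

*Adapter scan.* Seed-and-extend at word size 4: each exact shared 4-mer
is extended ungapped in both directions (match +1, mismatch −2) to the
maximal score, with an X-drop of 20 to bound the walk; one extension is
computed per diagonal. A span is reported when its Karlin–Altschul
e-value `K·m·n·e^(−λS)` ≤ 0.01, with λ = 1.28 and K = 0.46 (the standard
ungapped DNA values for this scoring; both configurable). Overlapping
spans are merged. This approximates a word-size-4 nucleotide search well
enough that planted-truth recall is the tested property; e-value
agreement with any external aligner is not claimed.

*Clipping.* Adapter spans are excised and the **longest single surviving
segment** becomes the new contig sequence (the alternative — keeping all
segments — would multiply contig records; we keep one and record the clip
in the report). The survivor must still reach the 200-nt minimum report
length, the only prior cutoff in the protocol; both cutoffs are
configurable.

*Triage.* Stage 1 accepts a contig on any reference-genome hit passing
**all** of e-value < 1e-5, alignment length > 100, identity > 80%
(strict inequalities). Stage 2 examines the best general-database hit —
max bitscore, ties broken by min e-value, then max alignment length, then
subject id (an invented but deterministic order). A bacterial best hit
removes the contig; since only bacterial best hits are stated to be
removed, a non-bacterial, non-plant best hit is conservatively **kept**,
as is a contig with no hits at all. A subject missing from the taxonomy
map raises an error rather than silently keeping the contig. Taxonomy is
a flat two-column subject → group map; the group literal `Bacteria`
triggers removal.

*Length filter.* `length < 400` is removed; a 400-nt contig survives.

The cleanup report checks count conservation (`out = in − removals`) at
every stage at run time.

## Representative peptides (`txpolish.orfselect`)

Six frames are enumerated; every maximal stop-to-stop open segment
yields the longest Met-initiated ORF it contains and, when the segment
does not start with Met, the full segment as a 5'-partial candidate.
Candidates below the 30-aa enumeration floor are dropped — an efficiency
choice safely below the 100-aa keep rule. CDS coordinates are 1-based
inclusive on the forward strand and **include the stop codon** when one
terminates the ORF (common predictor convention, stated in the GFF3
header). Codons containing N translate to X; the standard genetic code
only.

Selection per contig: if any candidate has a database hit with e-value
below 1e-10, the candidate with the highest bitscore wins (ties: longer
peptide, then lower start coordinate); otherwise the longest
Met-initiated candidate wins (ties: lower start), falling back to the
longest candidate only when no Met candidate exists — 5'-partials are
enumerated so a hit can rescue them but cannot win the length path over a
Met candidate. The single e-value named for database significance serves
both as override and keep threshold. The keep rule is strict: peptide
length > 100 aa (so a 100-aa peptide without a hit is dropped;
configurable) or a significant hit.

## RBH annotation (`txpolish.annotate`)

Per query the best hit is the maximum-bitscore row; multiple HSPs to the
same subject collapse to the best one first, and a remaining bitscore tie
across different subjects **voids** the query. Voiding (rather than
arbitrary tie-keeping) is our policy choice: an ambiguous best hit is not
an ortholog call, and the behaviour is deterministic. No e-value
pre-filter is applied by default (one is available). RBH pairs require
best-hit agreement in both directions and are emitted sorted by query.
GO terms, when supplied, are merged in as a ready-made table, never
computed.

## Assembly statistics (`txpolish.asmstats`)

Nx uses the ≥ convention at the cumulative boundary on descending-sorted
lengths. ExNy sorts by expression descending with ties broken by length
descending then id ascending (the protocol is silent; the tie-break is
for determinism only), takes the smallest prefix reaching E% of total
expression, and computes Nx over that prefix. Expression units are taken
as given — ExNy is invariant to rescaling, so counts vs TPM changes
nothing for a fixed vector; whether gene- or isoform-level expression is
used is the caller's choice and the functions operate on whatever vector
is supplied.

## Tissue specificity (`txpolish.expr`)

Presence is `count ≥ threshold` with a default of 1 read — no detection
threshold is part of the published Venn figure, so the value is a
documented decision surfaced in the output metadata, and threshold 0
(everything present) is an allowed edge. Each transcript present
somewhere belongs to exactly one of the 2^k − 1 regions; all-absent
transcripts are tallied separately so region sums plus the absent count
always equal the transcript total.

## Synthetic data (`txpolish.synthio`)

The generator emulates the *structure* of the real inputs, not their
biology: contig base composition is i.i.d. at a target GC (plant-like
0.40; bacterial-like contigs resequenced at 0.65 purely for realism —
triage uses only the hit tables, never composition); hit tables are
fabricated to be unambiguous for their planted label (passing reference
hits for plant contigs, bacterial best hits for contaminants, silence for
no-hit contigs); adapter fragments are overwritten into contigs at ≥ 75%
of the 33-nt adapter length so word-size-4 detection is well-posed;
CDS-bearing contigs are built by encoding a random peptide with random
synonymous codons between random flanks, and a brute-force ATG scan over
all six frames verifies at generation time that the planted CDS is
strictly the longest Met-initiated ORF, resampling otherwise; read
qualities follow constant or step profiles with small jitter, with the
true trim point computed by an independent vectorised window-scan oracle.
Feature counts are exact (a 20% bacterial fraction on 500 contigs plants
exactly 100), planted where the spec of a run calls for designed subsets.

Consequently, passing tests demonstrate that the *rules* are implemented
correctly and recover planted truth; they do not demonstrate robustness
to real-data phenomena the generator omits: sequencing error models,
chimeric or fragmented contigs, ambiguous contamination evidence,
isoform redundancy, or expression noise. Truth intervals are stored
0-based half-open in manifests and converted to 1-based inclusive only at
GFF3 emission.

All artifacts are byte-deterministic given seed and parameters; the
pipeline itself writes no timestamps, so `run` is byte-reproducible.

## Problem sizes

Desk-scale sizes keep every check fast while leaving no rule untested:
10,000 read pairs for trim-truth agreement; 500 contigs (10% adapters,
20% bacterial, 10% no-hit) for cleanup round-trip; 1,000 random
sequences ≤ 60 nt plus 200 planted-CDS contigs for ORF checks; 1,000
random score matrices ≤ 10×10 for RBH; 10,000 length multisets ≤ 12 for
Nx; 1,000 random presence matrices ≤ 100×5 for the Venn partition; a
2,000-contig lognormal-expression assembly for E90N50/E90N90.

## Known limitations

- Adapter clipping in reads implements simple mode only (no palindrome
  read-through detection for overlapping mates).
- The in-contig adapter scanner's e-values are approximate
  (Karlin–Altschul with fixed λ, K; no edge-effect or length corrections).
- Single-end trimming is incidental, not a supported mode.
- Triage recognises one removable group (`Bacteria`); finer taxonomy and
  other contaminant classes reduce to keep/remove via the map.
- External ORF predictor integration accepts coordinate-identical merges
  only; no consensus scoring across predictors.
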