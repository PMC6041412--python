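"""Six-frame ORF enumeration and representative peptide selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txpolish.orfselect import (
    KeepReason,
    OrfCandidate,
    SelectionReason,
    SequenceFormatError,
    SwissProtHit,
    find_orfs,
    merge_candidates,
    revcomp,
    select_representative,
    translate,
    write_outputs,
)

_dna = st.text(alphabet="ACGT", min_size=3, max_size=60)


def brute_force_orfs(contig_id, seq, min_aa):
    """Oracle enumerator: for every (strand, frame) translate the framed
    sequence codon by codon and emit, per stop-delimited open segment, the
    full segment and its first-Met suffix, computing coordinates directly."""
    out = set()
    n = len(seq)
    for strand in ("+", "-"):
        s = revcomp(seq) if strand == "-" else seq
        for frame in (1, 2, 3):
            codon_starts = list(range(frame - 1, n - 2, 3))
            peps = [translate(s[i : i + 3]) for i in codon_starts]
            seg = []
            for idx, aa in enumerate(peps + ["*"]):
                if aa == "*" and idx < len(peps):
                    closing = True
                    has_stop = True
                elif idx == len(peps):
                    closing = True
                    has_stop = False
                else:
                    seg.append((idx, aa))
                    continue
                if seg:
                    pep = "".join(a for _, a in seg)
                    first = codon_starts[seg[0][0]]
                    last_excl = codon_starts[seg[-1][0]] + 3 + (3 if has_stop else 0)
                    variants = [(first, pep, pep.startswith("M"))]
                    m = pep.find("M")
                    if m > 0:
                        variants.append((codon_starts[seg[m][0]], pep[m:], True))
                    for ws_start, pep_v, met in variants:
                        if len(pep_v) < min_aa:
                            continue
                        if strand == "+":
                            coords = (ws_start + 1, last_excl)
                        else:
                            coords = (n - last_excl + 1, n - ws_start)
                        out.add((strand, coords[0], coords[1], pep_v, met, has_stop))
                seg = []
            del seg
    return out


class TestTranslate:
    @pytest.mark.parametrize(
        "dna,frame,strand,expected",
        [
            ("ATGAAA", 1, "+", "MK"),
            ("ATGNNN", 1, "+", "MX"),
            ("ATGAAATAA", 1, "+", "MK*"),
            ("CATGAA", 2, "+", "M"),
        ],
    )
    def test_standard_code(self, dna, frame, strand, expected):
        assert translate(dna, frame, strand) == expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(SequenceFormatError):
            translate("ATGRYK")

    @given(st.text(alphabet="ACGT", min_size=3, max_size=90))
    @settings(derandomize=True, max_examples=200)
    def test_minus_strand_equals_translate_of_revcomp(self, seq):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))  # independent revcomp
        assert translate(seq, 1, "-") == translate(rc, 1, "+")


class TestFindOrfs:
    def test_simple_met_orf_with_stop(self):
        cands = find_orfs("c", "ATGAAATAA", min_aa=2)
        met = [c for c in cands if c.met_initiated and c.strand == "+"]
        assert len(met) == 1
        assert (met[0].peptide, met[0].cds_start, met[0].cds_end) == ("MK", 1, 9)

    def test_minus_strand_coordinates(self):
        cands = find_orfs("c", "TTACATGGGCAT", min_aa=3)
        hit = [c for c in cands if c.peptide == "MPM"]
        assert len(hit) == 1
        assert (hit[0].strand, hit[0].cds_start, hit[0].cds_end) == ("-", 1, 12)

    def test_no_atg_no_met_candidates(self):
        assert all(not c.met_initiated for c in find_orfs("c", "CCCCCCCCC", min_aa=1))

    @given(_dna, st.integers(1, 5))
    @settings(derandomize=True, max_examples=400)
    def test_matches_brute_force_enumerator(self, seq, min_aa):
        got = {
            (c.strand, c.cds_start, c.cds_end, c.peptide, c.met_initiated, c.has_stop)
            for c in find_orfs("c", seq, min_aa=min_aa)
        }
        assert got == brute_force_orfs("c", seq, min_aa)


class TestMerge:
    def _cand(self, start=1, end=9, pep="MK", source="internal"):
        return OrfCandidate("c", "+", 1, start, end, pep, True, True, (source,))

    def test_identical_candidates_collapse_with_merged_sources(self):
        merged = merge_candidates([self._cand()], [self._cand(source="external:tool")])
        assert len(merged) == 1
        assert merged[0].sources == ("internal", "external:tool")

    def test_disjoint_sets_conserved(self):
        a = [self._cand(start=1, end=9), self._cand(start=4, end=9, pep="K")]
        b = [self._cand(start=7, end=9, pep="")]
        assert len(merge_candidates(a, b)) == 3

    def test_merge_with_empty_is_identity(self):
        a = [self._cand()]
        assert merge_candidates(a, []) == a


class TestSelectRepresentative:
    def _cand(self, aa, start=1, met=True):
        pep = ("M" if met else "K") + "A" * (aa - 1)
        return OrfCandidate("c", "+", 1, start, start + aa * 3 + 2, pep, met, True)

    def test_hit_overrides_longest_met(self):
        a = self._cand(160)
        b = self._cand(120, start=700)
        hit = SwissProtHit(b.key, "sp|P1", 200.0, 1e-30)
        rep = select_representative([a, b], {b.key: hit})
        assert rep.candidate is b
        assert rep.selection_reason is SelectionReason.HIT_SCORE
        assert rep.kept

    def test_longest_met_without_hits(self):
        a, b = self._cand(160), self._cand(120, start=700)
        rep = select_representative([a, b])
        assert rep.candidate is a
        assert rep.selection_reason is SelectionReason.LONGEST_MET
        assert rep.keep_reason is KeepReason.LENGTH_GT_100

    def test_short_no_hit_selected_but_not_kept(self):
        rep = select_representative([self._cand(80)])
        assert not rep.kept
        assert rep.keep_reason is KeepReason.NOT_KEPT

    def test_short_with_significant_hit_kept(self):
        c = self._cand(80)
        rep = select_representative([c], {c.key: SwissProtHit(c.key, "sp", 90.0, 1e-15)})
        assert rep.kept
        assert rep.keep_reason is KeepReason.HIT_E_LT_1e10

    def test_higher_bitscore_wins_between_hit_candidates(self):
        a, b = self._cand(150), self._cand(110, start=700)
        hits = {
            a.key: SwissProtHit(a.key, "s1", 250.0, 1e-40),
            b.key: SwissProtHit(b.key, "s2", 300.0, 1e-40),
        }
        assert select_representative([a, b], hits).candidate is b

    def test_insignificant_hit_does_not_override(self):
        a, b = self._cand(160), self._cand(120, start=700)
        hits = {b.key: SwissProtHit(b.key, "s", 50.0, 1e-3)}
        assert select_representative([a, b], hits).candidate is a

    def test_partial_candidates_cannot_win_over_met(self):
        met = self._cand(50)
        partial = self._cand(200, start=700, met=False)
        assert select_representative([met, partial]).candidate is met

    def test_partial_wins_when_no_met_exists(self):
        partial = self._cand(120, met=False)
        rep = select_representative([partial])
        assert rep.candidate is partial
        assert rep.kept

    def test_keep_boundary_is_strict(self):
        assert not select_representative([self._cand(100)]).kept
        assert select_representative([self._cand(101)]).kept

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_representative([])


class TestWriteOutputs:
    def test_gff_and_fasta_round_trip(self, tmp_path, planted_orf_fixture):
        contigs, manifest = planted_orf_fixture
        subset = contigs[:25]
        reps = [
            select_representative(find_orfs(c.id, c.sequence)) for c in subset
        ]
        fa, gff = tmp_path / "p.fa", tmp_path / "c.gff3"
        write_outputs(reps, fa, gff)
        seqs = {c.id: c.sequence for c in subset}
        peptides = {}
        with open(fa) as fh:
            for line in fh:
                if line.startswith(">"):
                    pid = line[1:].strip()
                else:
                    peptides[pid] = line.strip()
        n_cds = 0
        with open(gff) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                seqid, _, ftype, start, end, _, strand, phase, attrs = line.split("\t")
                assert ftype == "CDS" and phase == "0"
                cds = seqs[seqid][int(start) - 1 : int(end)]
                if strand == "-":
                    cds = revcomp(cds)
                assert translate(cds).rstrip("*") == peptides[attrs.strip().split("=")[1]]
                n_cds += 1
        assert n_cds == len(peptides) == len(subset)
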