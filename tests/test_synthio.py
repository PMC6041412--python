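"""Properties of the synthetic fixture generator and its truth manifests."""

import json

import numpy as np
import pytest

from txpolish import synthio
from txpolish.contigfilter import scan_adapters
from txpolish.orfselect import find_orfs, revcomp, select_representative
from txpolish.readtrim import sliding_window_trim
from txpolish.synthio import (
    DEFAULT_ADAPTER,
    FixtureManifest,
    make_contigs,
    make_count_matrix,
    make_read_pairs,
    plant_adapters,
    plant_contaminants,
    plant_orfs,
    write_fasta,
)


class TestMakeContigs:
    def test_identical_seed_identical_bytes(self, tmp_path):
        for name in ("a.fa", "b.fa"):
            contigs, _ = make_contigs(100, (300, 3000), gc=0.4, seed=42)
            write_fasta(contigs, tmp_path / name)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_degenerate_range(self):
        contigs, _ = make_contigs(1, (500, 500), seed=0)
        assert len(contigs) == 1 and len(contigs[0]) == 500

    def test_gc_within_binomial_bound(self):
        contigs, _ = make_contigs(1000, (300, 400), gc=0.4, seed=10)
        bases = "".join(c.sequence for c in contigs)
        observed = (bases.count("G") + bases.count("C")) / len(bases)
        # ~350k bases: 3 binomial sigmas are well under 0.02
        assert abs(observed - 0.4) < 0.02

    @pytest.mark.parametrize("kwargs", [{"n": 0}, {"length_range": (10, 5)}, {"gc": 0.0}])
    def test_parameter_validation(self, kwargs):
        defaults = dict(n=5, length_range=(100, 200), gc=0.5, seed=0)
        with pytest.raises(ValueError):
            make_contigs(**{**defaults, **kwargs})


class TestPlantAdapters:
    def test_rate_zero_is_identity(self):
        contigs, _ = make_contigs(10, (300, 500), seed=1)
        planted, manifest = plant_adapters(contigs, rate=0.0, seed=2)
        assert [c.sequence for c in planted] == [c.sequence for c in contigs]
        assert all(not e["adapter_spans"] for e in manifest.records.values())

    def test_rate_one_forces_all(self):
        contigs, _ = make_contigs(10, (300, 500), seed=1)
        _, manifest = plant_adapters(contigs, rate=1.0, seed=2)
        spans = [e["adapter_spans"] for e in manifest.records.values()]
        assert sum(len(s) for s in spans) == 10

    def test_planted_fragment_at_recorded_span(self):
        contigs, _ = make_contigs(20, (400, 900), seed=4)
        planted, manifest = plant_adapters(contigs, rate=0.5, seed=5)
        seqs = {c.id: c.sequence for c in planted}
        checked = 0
        for cid, entry in manifest.records.items():
            for start, end in entry["adapter_spans"]:
                assert seqs[cid][start:end] in DEFAULT_ADAPTER
                assert end - start >= int(np.ceil(0.75 * len(DEFAULT_ADAPTER)))
                checked += 1
        assert checked == 10

    def test_scan_recall_on_planted_spans(self):
        contigs, _ = make_contigs(200, (500, 2000), seed=6)
        planted, manifest = plant_adapters(contigs, rate=0.5, seed=7)
        seqs = {c.id: c.sequence for c in planted}
        found = total = 0
        for cid, entry in manifest.records.items():
            truth = entry["adapter_spans"]
            if not truth:
                continue
            spans = scan_adapters(seqs[cid], [DEFAULT_ADAPTER])
            for t_start, t_end in truth:
                total += 1
                if any(s < t_end and t_start < e for s, e in spans):
                    found += 1
        assert total == 100
        assert found / total >= 0.95

    def test_adapter_longer_than_shortest_contig_rejected(self):
        contigs, _ = make_contigs(3, (20, 25), seed=0)
        with pytest.raises(ValueError):
            plant_adapters(contigs, rate=1.0, seed=0)


class TestPlantContaminants:
    def test_zero_bacterial_fraction_no_bacterial_best_hits(self):
        contigs, _ = make_contigs(50, (400, 800), seed=3)
        _, _, nt_hits, taxonomy, manifest = plant_contaminants(
            contigs, bacterial_fraction=0.0, seed=4
        )
        best_subjects = {h.sseqid for h in nt_hits}
        assert all(taxonomy[s] != "Bacteria" for s in best_subjects)
        labels = {e["contamination"] for e in manifest.records.values()}
        assert "BACTERIAL_REMOVED" not in labels

    def test_forced_bacterial_count(self):
        contigs, _ = make_contigs(100, (400, 800), seed=3)
        _, _, _, _, manifest = plant_contaminants(contigs, bacterial_fraction=0.2, seed=4)
        labels = [e["contamination"] for e in manifest.records.values()]
        assert labels.count("BACTERIAL_REMOVED") == 20

    def test_taxonomy_covers_all_nt_subjects(self):
        contigs, _ = make_contigs(60, (400, 800), seed=5)
        _, _, nt_hits, taxonomy, _ = plant_contaminants(
            contigs, bacterial_fraction=0.3, nonbacterial_fraction=0.1, seed=6
        )
        assert {h.sseqid for h in nt_hits} <= set(taxonomy)


class TestPlantOrfs:
    def test_construction_places_cds_at_recorded_coordinates(self):
        contigs, manifest = plant_orfs(20, peptide_lengths=(30, 60), seed=2)
        from txpolish.orfselect import translate

        for contig in contigs:
            entry = manifest.records[contig.id]
            start, end = entry["cds_span"]
            cds = contig.sequence[start:end]
            if entry["cds_strand"] == "-":
                cds = revcomp(cds)
            assert cds.startswith("ATG")
            assert translate(cds) == entry["peptide"] + "*"

    def test_strand_mix_deterministic_and_balanced(self):
        _, m1 = plant_orfs(40, peptide_lengths=(20, 40), strand_mix=0.5, seed=9)
        _, m2 = plant_orfs(40, peptide_lengths=(20, 40), strand_mix=0.5, seed=9)
        strands1 = [e["cds_strand"] for e in m1.records.values()]
        assert strands1 == [e["cds_strand"] for e in m2.records.values()]
        assert strands1.count("-") == 20

    def test_recovery_by_orf_selection(self, planted_orf_fixture):
        contigs, manifest = planted_orf_fixture
        recovered = 0
        for contig in contigs:
            entry = manifest.records[contig.id]
            rep = select_representative(find_orfs(contig.id, contig.sequence))
            start0, end0 = entry["cds_span"]
            if (
                rep.candidate.cds_start == start0 + 1
                and rep.candidate.cds_end == end0
                and rep.candidate.strand == entry["cds_strand"]
            ):
                recovered += 1
        assert recovered / len(contigs) >= 0.99

    def test_infeasible_peptide_length_rejected(self):
        with pytest.raises(ValueError):
            plant_orfs(5, peptide_lengths=(5, 8), seed=0)


class TestMakeCountMatrix:
    def test_forced_design(self):
        counts, truth = make_count_matrix(
            ["root", "stem"], 20, {"root": 5, "stem": 2}, seed=0
        )
        assert truth.regions[frozenset(["root"])] == 5
        assert truth.regions[frozenset(["stem"])] == 2
        assert truth.regions[frozenset(["root", "stem"])] == 13
        # designed transcripts are nonzero only in their tissue
        root_only = counts[(counts["root"] > 0) & (counts["stem"] == 0)]
        assert len(root_only) == 5

    def test_design_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            make_count_matrix(["a"], 3, {"a": 4}, seed=0)

    def test_deterministic(self):
        a, _ = make_count_matrix(["x", "y"], 15, {"x": 3}, seed=5)
        b, _ = make_count_matrix(["x", "y"], 15, {"x": 3}, seed=5)
        assert a.equals(b)


class TestMakeReadPairs:
    def test_constant_high_quality_trims_nothing(self):
        r1, r2, manifest = make_read_pairs(
            20, quality_profile=("constant", 40), jitter=0, seed=0
        )
        assert all(t["trim1"] == 150 and t["trim2"] == 150 for t in manifest.reads.values())

    def test_pairing_invariant(self):
        r1, r2, _ = make_read_pairs(30, seed=1)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert a.id[:-2] == b.id[:-2]
            assert (a.mate, b.mate) == (1, 2)

    def test_step_profile_truth_matches_independent_trimmer(self):
        r1, r2, manifest = make_read_pairs(200, seed=2)
        for reads, key in ((r1, "trim1"), (r2, "trim2")):
            for read in reads:
                truth = manifest.reads[read.id[:-2]][key]
                assert len(sliding_window_trim(read)) == truth

    def test_adapter_rate_records_positions(self):
        r1, _, manifest = make_read_pairs(50, adapter_rate=0.2, seed=3)
        seqs = {r.id[:-2]: r.sequence for r in r1}
        with_adapter = [t for t in manifest.reads.values() if "adapter1" in t]
        assert len(with_adapter) == 10
        for stem, truth in manifest.reads.items():
            if "adapter1" in truth:
                pos = truth["adapter1"]
                assert seqs[stem][pos:] == DEFAULT_ADAPTER[: 150 - pos]


class TestManifest:
    def test_json_round_trip(self, tmp_path):
        contigs, manifest = make_contigs(5, (300, 400), seed=1)
        _, manifest = plant_adapters(contigs, rate=0.4, seed=2, manifest=manifest)
        path = tmp_path / "m.json"
        manifest.to_json(path)
        back = FixtureManifest.from_json(path)
        assert back.seed == manifest.seed
        assert back.records == json.loads(json.dumps(manifest.records))

    def test_end_to_end_fixture_deterministic(self, tmp_path):
        import hashlib

        digests = []
        for name in ("f1", "f2"):
            outdir = tmp_path / name
            synthio.make_end_to_end(outdir, seed=33, n_contigs=12, n_pairs=6)
            digest = {
                p.name: hashlib.md5(p.read_bytes()).hexdigest()
                for p in sorted(outdir.iterdir())
            }
            digests.append(digest)
        assert digests[0] == digests[1]
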