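import json

import pandas as pd
import pytest

import stitchkit as sk
from stitchkit.errors import ParameterError
from stitchkit.reports import primer_map_rows, primers_frame, summary_frame

from .test_design import loose_params


class TestSummarize:
    def test_single_candidate_collapses(self, fixture_record):
        params = loose_params(search_area_5p=20, fwd_size=20)
        cands = sk.enumerate_candidates(fixture_record, params, "forward")
        assert len(cands) == 1
        summary = sk.summarize(cands)
        for m in summary.metrics.values():
            assert m.minimum == m.average == m.maximum

    def test_empty_is_explicitly_empty(self):
        summary = sk.summarize([])
        assert summary.empty and summary.metrics == {}
        assert summary_frame([summary]).empty

    def test_average_of_two(self, fixture_record):
        import dataclasses

        params = loose_params(search_area_5p=40, fwd_size=20)
        cands = sk.enumerate_candidates(fixture_record, params, "forward")[:2]
        cands = [
            dataclasses.replace(cands[0], tm_celsius=55.0),
            dataclasses.replace(cands[1], tm_celsius=59.0),
        ]
        summary = sk.summarize(cands)
        assert summary.metrics["tm"].average == pytest.approx(57.0)
        for m in summary.metrics.values():
            assert m.minimum <= m.average <= m.maximum

    def test_only_passing_candidates_counted(self, fixture_record):
        params = loose_params(gc_min=49.9, gc_max=50.1)
        cands = sk.enumerate_candidates(fixture_record, params, "forward")
        summary = sk.summarize(cands)
        assert summary.n_passing == sum(c.passes for c in cands)


class TestPinnedPrimer:
    def test_forward_pin_is_verbatim_slice(self, fixture_record):
        params = loose_params()
        pin = sk.score_pinned_primer(fixture_record, 1, 18, "forward", params)
        assert pin.core_seq == fixture_record.seq[:18]
        assert pin.tm_celsius is not None and pin.self_report is not None

    def test_reverse_pin_is_reverse_complement(self, fixture_record):
        params = loose_params()
        pin = sk.score_pinned_primer(fixture_record, 101, 120, "reverse", params)
        assert pin.core_seq == sk.reverse_complement(fixture_record.seq[100:120])

    def test_out_of_range_rejected(self, fixture_record):
        params = loose_params()
        with pytest.raises(ParameterError):
            sk.score_pinned_primer(
                fixture_record, 1, fixture_record.length + 1, "forward", params
            )


class TestFixtureGenerator:
    def test_same_seed_same_sequence(self):
        a = sk.generate_fixture(seed=1, length=500)
        b = sk.generate_fixture(seed=1, length=500)
        assert a.seq == b.seq
        assert a.seq != sk.generate_fixture(seed=2, length=500).seq

    def test_gc_fraction_within_binomial_bound(self):
        rec = sk.generate_fixture(seed=3, length=10000, gc_fraction=0.5)
        gc = sum(rec.seq.count(b) for b in "GC") / rec.length
        assert 0.48 <= gc <= 0.52

    def test_planted_repeat_is_detected(self):
        rec = sk.generate_fixture(seed=4, length=300, repeat_insert="TTTT")
        assert "TTTT" in rec.seq
        pos = rec.seq.index("TTTT")
        assert sk.is_repetitive(rec.seq[max(0, pos - 5):pos + 9])

    def test_n_placement(self):
        rec = sk.generate_fixture(seed=5, length=300, n_count=4)
        assert rec.seq.count("N") == 4

    def test_min_length_enforced(self):
        with pytest.raises(ParameterError):
            sk.generate_fixture(seed=1, length=10)


class TestRunDesign:
    def test_default_outputs(self, fixture_fasta, tmp_path):
        out = tmp_path / "out"
        manifest = sk.run_design(fixture_fasta, sk.DesignParameters(), out)
        for key in ("forward", "reverse", "pairs"):
            assert manifest[key].exists()
        fwd = pd.read_csv(manifest["forward"], sep="\t")
        assert not fwd.empty and set(["name", "start", "end", "tm"]) <= set(fwd.columns)

    def test_all_outputs(self, fixture_fasta, tmp_path):
        manifest = sk.run_design(
            fixture_fasta, sk.DesignParameters(), tmp_path / "out",
            outputs={"all"}, pins=[(1, 18, "forward")],
        )
        for key in ("forward", "reverse", "pairs", "composition", "summary",
                    "map", "map_bed", "json", "pinned"):
            assert key in manifest and manifest[key].exists()

    def test_unreadable_input_raises(self, tmp_path):
        with pytest.raises(OSError):
            sk.run_design(tmp_path / "missing.fa", sk.DesignParameters(), tmp_path)

    def test_zero_passing_primers_writes_headers(self, fixture_fasta, tmp_path):
        params = sk.DesignParameters(gc_min=99.0, gc_max=100.0)
        manifest = sk.run_design(fixture_fasta, params, tmp_path / "out")
        pairs = pd.read_csv(manifest["pairs"], sep="\t")
        assert pairs.empty and list(pairs.columns)

    def test_json_bundle_round_trips_tables(self, fixture_fasta, tmp_path):
        manifest = sk.run_design(
            fixture_fasta, sk.DesignParameters(), tmp_path / "out",
            outputs={"tables", "pairs", "json"},
        )
        bundle = json.loads(manifest["json"].read_text())
        fwd_tsv = pd.read_csv(manifest["forward"], sep="\t", keep_default_na=False)
        fwd_json = pd.DataFrame(bundle["forward_primers"]).astype(fwd_tsv.dtypes)
        pd.testing.assert_frame_equal(fwd_tsv, fwd_json)
        pairs_tsv = pd.read_csv(manifest["pairs"], sep="\t", keep_default_na=False)
        pairs_json = pd.DataFrame(bundle["pairs"]).astype(pairs_tsv.dtypes)
        pd.testing.assert_frame_equal(pairs_tsv, pairs_json)

    def test_map_rows_match_tables(self, fixture_fasta, tmp_path):
        manifest = sk.run_design(
            fixture_fasta, sk.DesignParameters(), tmp_path / "out",
            outputs={"tables", "pairs", "map"},
        )
        fwd = pd.read_csv(manifest["forward"], sep="\t")
        rev = pd.read_csv(manifest["reverse"], sep="\t")
        map_df = pd.read_csv(manifest["map"], sep="\t")
        assert len(map_df) == len(fwd) + len(rev)
        assert list(map_df["start"]) == sorted(map_df["start"])
        bed = manifest["map_bed"].read_text().strip().splitlines()
        assert len(bed) == len(map_df)
        for line, (_, row) in zip(
            sorted(bed, key=lambda l: (int(l.split("\t")[1]), l.split("\t")[3])),
            map_df.sort_values(["start", "name"]).iterrows(),
        ):
            chrom, start0, end0, name, _, strand = line.split("\t")
            assert int(start0) == row["start"] - 1 and int(end0) == row["end"]

    def test_mutant_mode_writes_oligos(self, fixture_fasta, tmp_path):
        manifest = sk.run_design(
            fixture_fasta, sk.DesignParameters(), tmp_path / "out",
            mutant_seq="GATTACA",
        )
        text = manifest["mutant"].read_text()
        assert "TGTAATC" in text
        fwd = pd.read_csv(manifest["forward"], sep="\t")
        assert len(fwd) == 1

    def test_overlap_attaches_to_reverse_table(self, fixture_fasta, tmp_path):
        manifest = sk.run_design(
            fixture_fasta, sk.DesignParameters(), tmp_path / "out",
            overlap_name="GFP",
        )
        rev = pd.read_csv(manifest["reverse"], sep="\t")
        tail = sk.get_overlap("GFP").seq
        assert all(s.startswith(tail) for s in rev["full_sequence"])
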