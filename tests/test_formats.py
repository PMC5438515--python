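"""GEN / VCF / sample-file parsing, compression handling, range selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survscan.errors import DataError
from survscan.formats import (clean_prob_triples, open_genotype_stream,
                              read_gen_records, read_sample_file,
                              read_vcf_records, write_gen)

from conftest import make_record


def _random_records(rng, n_snps=5, n_subjects=4):
    recs = []
    for j in range(n_snps):
        probs = rng.dirichlet(np.ones(3), size=n_subjects)
        recs.append(make_record(probs, snp_id=f"s{j}", rs_id=f"rs{j}",
                                position=(j + 1) * 100))
    return recs


class TestGenotypeStream:
    @pytest.mark.parametrize("compression", ["none", "gzip", "zip"])
    def test_compression_invariance(self, rng, gen_file_factory, compression):
        """Plain, gzip and zip inputs yield byte-identical line streams."""
        recs = _random_records(rng)
        path = gen_file_factory(recs, compression=compression)
        lines = list(open_genotype_stream(path))
        plain = gen_file_factory(recs, compression="none", name="ref.gen")
        assert lines == list(open_genotype_stream(plain))
        assert len(lines) == 5

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(DataError, match="no/such/file"):
            list(open_genotype_stream(tmp_path / "no" / "such" / "file.gen"))

    def test_corrupt_gzip_is_fatal(self, tmp_path):
        bad = tmp_path / "bad.gen.gz"
        bad.write_bytes(b"\x1f\x8bthis is not a gzip stream")
        with pytest.raises(DataError):
            list(open_genotype_stream(bad))


class TestGenRecords:
    def test_round_trip(self, rng, gen_file_factory):
        """Writing then re-reading preserves metadata exactly, probs to 6 dp."""
        recs = _random_records(rng, n_snps=3, n_subjects=6)
        path = gen_file_factory(recs)
        back = list(read_gen_records(open_genotype_stream(path), 6,
                                     chromosome_label="7"))
        assert [(r.snp_id, r.rs_id, r.position_bp, r.allele_a, r.allele_b)
                for r in back] == \
               [(r.snp_id, r.rs_id, r.position_bp, r.allele_a, r.allele_b)
                for r in recs]
        assert all(r.chromosome == "7" for r in back)
        for orig, rec in zip(recs, back):
            # renormalisation absorbs the 6-decimal rounding of each triple
            np.testing.assert_allclose(rec.probs, orig.probs, atol=2e-6)

    @pytest.mark.parametrize("start,stop,expected", [
        (0, 9, 10), (3, 5, 3), (0, 0, 1), (9, 9, 1), (7, 100, 3),
    ])
    def test_line_range_window(self, rng, gen_file_factory, start, stop, expected):
        recs = _random_records(rng, n_snps=10)
        path = gen_file_factory(recs)
        got = list(read_gen_records(open_genotype_stream(path), 4,
                                    line_start=start, line_stop=stop))
        assert len(got) == expected
        assert [r.snp_id for r in got] == [f"s{j}" for j in range(start, min(stop, 9) + 1)]

    @given(st.integers(0, 9), st.integers(0, 9))
    @settings(max_examples=25, deadline=None)
    def test_range_selection_is_a_pure_filter(self, a, b):
        """Output of any (a, b) window equals the slice [a..b] of the full run."""
        if a > b:
            a, b = b, a
        rng = np.random.default_rng(7)
        recs = _random_records(rng, n_snps=10)
        lines = ["{} {} {} {} {} ".format(r.snp_id, r.rs_id, r.position_bp,
                                          r.allele_a, r.allele_b)
                 + " ".join(f"{p:.6f}" for p in r.probs.ravel())
                 for r in recs]
        full = [r.snp_id for r in read_gen_records(iter(lines), 4)]
        window = [r.snp_id for r in read_gen_records(iter(lines), 4,
                                                     line_start=a, line_stop=b)]
        assert window == full[a:b + 1]

    def test_bp_window(self, rng, gen_file_factory):
        recs = [make_record(rng.dirichlet(np.ones(3), size=2), snp_id=f"s{p}",
                            position=p) for p in (100, 200, 300)]
        path = gen_file_factory(recs)
        got = list(read_gen_records(open_genotype_stream(path), 2,
                                    bp_start=150, bp_stop=250))
        assert [r.position_bp for r in got] == [200]

    def test_wrong_field_count_cites_line(self):
        lines = ["s1 rs1 100 A G 1 0 0", "s2 rs2 200 A G 1 0"]
        with pytest.raises(DataError, match="line 1"):
            list(read_gen_records(iter(lines), 1))

    def test_non_numeric_probability_is_fatal(self):
        lines = ["s1 rs1 100 A G 1 zero 0"]
        with pytest.raises(DataError, match="non-numeric"):
            list(read_gen_records(iter(lines), 1))


class TestProbCleanup:
    def test_shortfall_triple_marks_subject_missing(self):
        probs, missing = clean_prob_triples([[0.2, 0.3, 0.2], [1, 0, 0]])
        assert missing.tolist() == [True, False]
        assert np.isnan(probs[0]).all()

    def test_near_one_triples_are_renormalised(self):
        probs, missing = clean_prob_triples([[0.33, 0.33, 0.33]])
        assert not missing[0]
        assert probs[0].sum() == pytest.approx(1.0, abs=1e-12)

    @given(st.lists(st.tuples(*[st.floats(0, 1)] * 3), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_cleaned_triples_sum_to_one_or_are_missing(self, triples):
        probs, missing = clean_prob_triples(np.array(triples, dtype=float))
        ok = ~missing
        if ok.any():
            np.testing.assert_allclose(probs[ok].sum(axis=1), 1.0, atol=1e-9)
        assert np.isnan(probs[missing]).all()


SAMPLE = [
    "ID event_times censoring covariate1",
    "id1 2.5 1 0.3",
    "id2 1.0 0 1.2",
    "id3 4.0 1 NA",
    "id4 3.5 1 0.9",
    "id5 0.5 0 0.1",
]


class TestSampleFile:
    def test_basic_read(self, sample_file_factory):
        path = sample_file_factory(SAMPLE)
        tab = read_sample_file(path, "event_times", "censoring", ["covariate1"])
        assert tab.n_subjects == 5
        assert tab.subject_ids[0] == "id1"
        np.testing.assert_allclose(tab.time, [2.5, 1.0, 4.0, 3.5, 0.5])
        assert tab.missing_mask(["covariate1"]).tolist() == [False, False, True, False, False]
        assert tab.missing_mask([]).tolist() == [False] * 5

    def test_type_code_row_is_skipped(self, sample_file_factory):
        lines = [SAMPLE[0], "0 P B C"] + SAMPLE[1:]
        tab = read_sample_file(sample_file_factory(lines), "event_times",
                               "censoring", ["covariate1"])
        assert tab.n_subjects == 5

    def test_missing_column_lists_available(self, sample_file_factory):
        path = sample_file_factory(SAMPLE)
        with pytest.raises(DataError, match="not_a_column") as err:
            read_sample_file(path, "not_a_column", "censoring")
        assert "event_times" in str(err.value)

    def test_non_binary_event_rejected(self, sample_file_factory):
        lines = ["ID t c", "id1 1.0 2"]
        with pytest.raises(DataError, match="0/1"):
            read_sample_file(sample_file_factory(lines), "t", "c")

    def test_categorical_covariate_rejected(self, sample_file_factory):
        lines = ["ID t c arm", "id1 1.0 1 placebo", "id2 2.0 0 active"]
        with pytest.raises(DataError, match="binary"):
            read_sample_file(sample_file_factory(lines), "t", "c", ["arm"])


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def _write_vcf(tmp_path, body_lines):
    path = tmp_path / "data.vcf"
    path.write_text(VCF_HEADER + "\n".join(body_lines) + "\n")
    return path


class TestVcf:
    def test_gp_triples_pass_through(self, tmp_path):
        path = _write_vcf(tmp_path, [
            "1\t100\tv1\tA\tG\t.\t.\t.\tGT:GP\t0/0:1,0,0\t0/1:0,1,0\t1/1:0,0,1",
        ])
        (rec,) = read_vcf_records(path)
        assert rec.source_kind == "probabilities"
        np.testing.assert_allclose(rec.probs, np.eye(3)[[0, 1, 2]])
        assert (rec.allele_a, rec.allele_b) == ("A", "G")

    def test_hard_calls_embed_as_degenerate_triples(self, tmp_path):
        path = _write_vcf(tmp_path, [
            "1\t100\tv1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
        ])
        (rec,) = read_vcf_records(path)
        assert rec.source_kind == "hard_calls"
        np.testing.assert_allclose(rec.probs, np.eye(3)[[0, 1, 2]])

    def test_dosage_only_site(self, tmp_path):
        path = _write_vcf(tmp_path, [
            "1\t100\tv1\tA\tG\t.\t.\t.\tDS\t0.0\t1.2\t2.0",
        ])
        (rec,) = read_vcf_records(path)
        assert rec.source_kind == "dosages"
        np.testing.assert_allclose(rec.dosages, [0.0, 1.2, 2.0])

    def test_gp_takes_priority_over_ds_and_gt(self, tmp_path):
        path = _write_vcf(tmp_path, [
            "1\t100\tv1\tA\tG\t.\t.\t.\tGT:GP:DS\t0/0:0.9,0.1,0:1.9\t0/1:0,1,0:0.0\t1/1:0,0,1:0.0",
        ])
        (rec,) = read_vcf_records(path)
        assert rec.source_kind == "probabilities"
        np.testing.assert_allclose(rec.probs[0], [0.9, 0.1, 0.0])

    def test_multiallelic_site_skipped(self, tmp_path):
        path = _write_vcf(tmp_path, [
            "1\t100\tv1\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
            "1\t200\tv2\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
        ])
        recs = list(read_vcf_records(path))
        assert [r.snp_id for r in recs] == ["v2"]

    def test_missing_genotype_marks_subject(self, tmp_path):
        path = _write_vcf(tmp_path, [
            "1\t100\tv1\tA\tG\t.\t.\t.\tGT\t./.\t0/1\t1/1",
        ])
        (rec,) = read_vcf_records(path)
        assert rec.subject_missing.tolist() == [True, False, False]

    def test_bp_window_applies(self, tmp_path):
        path = _write_vcf(tmp_path, [
            f"1\t{pos}\tv{pos}\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1"
            for pos in (100, 200, 300)
        ])
        recs = list(read_vcf_records(path, bp_start=150, bp_stop=250))
        assert [r.position_bp for r in recs] == [200]


def test_write_gen_rejects_dosage_records(tmp_path, rng):
    from survscan.formats import GenotypeRecord

    rec = GenotypeRecord(snp_id="s", rs_id="r", chromosome="1", position_bp=1,
                         allele_a="A", allele_b="G", source_kind="dosages",
                         dosages=np.array([1.0]))
    with pytest.raises(DataError):
        write_gen([rec], tmp_path / "x.gen")
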