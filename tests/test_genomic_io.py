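import numpy as np
import pytest

from enhanseq import (
    FeatureMatrix,
    GenomicRegion,
    read_bed,
    read_fasta,
    read_feature_matrix,
    read_peaks,
    read_pwms,
    read_region_counts,
    write_feature_matrix,
)
from enhanseq.genomic_io import PWM, PeakSet, RegionReadCounts, write_bed


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFasta:
    def test_case_folding_and_concatenation(self, tmp_path):
        g = read_fasta(write(tmp_path, "a.fa", ">chr1\nacgt\nACGT\n"))
        assert g.sequences == {"chr1": "ACGTACGT"}
        assert g.lengths == {"chr1": 8}

    def test_ambiguity_codes_become_n(self, tmp_path):
        g = read_fasta(write(tmp_path, "a.fa", ">c\nACRT\n"))
        assert g.sequences["c"] == "ACNT"

    def test_multiple_records(self, tmp_path):
        g = read_fasta(write(tmp_path, "a.fa", ">a\nAA\n>b\nCC\n"))
        assert g.lengths == {"a": 2, "b": 2}

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_fasta(write(tmp_path, "a.fa", ""))

    def test_duplicate_names_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_fasta(write(tmp_path, "a.fa", ">a\nAA\n>a\nCC\n"))

    def test_out_of_bounds_fetch_is_error(self, tmp_path):
        g = read_fasta(write(tmp_path, "a.fa", ">a\nACGT\n"))
        with pytest.raises(ValueError):
            g.fetch("a", 2, 6)


class TestBed:
    def test_default_id_and_length(self, tmp_path):
        (r,) = read_bed(write(tmp_path, "r.bed", "chr1\t10\t110\n"))
        assert (r.id, r.length) == ("chr1:10-110", 100)

    def test_empty_interval_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_bed(write(tmp_path, "r.bed", "chr1\t5\t5\n"))

    def test_comment_and_track_lines_skipped(self, tmp_path):
        text = "track name=x\nchr1\t0\t5\n# a comment\nchr1\t10\t15\n"
        assert len(read_bed(write(tmp_path, "r.bed", text))) == 2

    def test_non_integer_coordinates_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_bed(write(tmp_path, "r.bed", "chr1\tx\t5\n"))

    def test_column4_used_as_id_and_label_applied(self, tmp_path):
        (r,) = read_bed(write(tmp_path, "r.bed", "chr1\t0\t5\tmyid\n"), "positive")
        assert (r.id, r.label) == ("myid", "positive")

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        regions = [GenomicRegion("chr2", 3, 9, "unlabeled", "x")]
        path = tmp_path / "w.bed"
        write_bed(regions, path)
        (r,) = read_bed(path)
        assert (r.chrom, r.start, r.end, r.id) == ("chr2", 3, 9, "x")

    def test_region_invariants(self):
        with pytest.raises(ValueError):
            GenomicRegion("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicRegion("chr1", -1, 5)


class TestPwms:
    def test_tsv_width_and_ids(self, tmp_path):
        text = ">M1\n8\t0\t0\t0\n0\t8\t0\t0\n"
        (p,) = read_pwms(write(tmp_path, "m.txt", text), "tsv")
        assert (p.id, p.width) == ("M1", 2)
        assert p.counts[0, 0] == 8 and p.counts[1, 1] == 8

    def test_jaspar_unequal_rows_rejected(self, tmp_path):
        text = ">M1\nA [ 1 2 3 ]\nC [ 1 2 ]\nG [ 1 2 3 ]\nT [ 1 2 3 ]\n"
        with pytest.raises(ValueError):
            read_pwms(write(tmp_path, "m.txt", text), "jaspar")

    def test_jaspar_parses_labelled_rows(self, tmp_path):
        text = ">MA01 TF1\nA [ 8 0 ]\nC [ 0 8 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        (p,) = read_pwms(write(tmp_path, "m.txt", text), "jaspar")
        assert p.consensus() == "AC"

    def test_transfac_three_blocks(self, tmp_path):
        block = "ID M{i}\nP0 A C G T\n01 8 0 0 0\n02 0 8 0 0\n//\n"
        text = "".join(block.replace("{i}", str(i)) for i in range(3))
        pwms = read_pwms(write(tmp_path, "m.txt", text), "transfac")
        assert [p.id for p in pwms] == ["M0", "M1", "M2"]

    def test_frequency_matrix_flagged(self, tmp_path):
        text = ">F\n0.7\t0.1\t0.1\t0.1\n0.25\t0.25\t0.25\t0.25\n"
        (p,) = read_pwms(write(tmp_path, "m.txt", text), "tsv")
        assert p.from_frequencies
        assert np.allclose(p.effective_counts(), p.counts * 100)

    def test_zero_column_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_pwms(write(tmp_path, "m.txt", ">M\n0\t0\t0\t0\n"), "tsv")


class TestPeaks:
    def test_unsorted_input_sorted(self, tmp_path):
        ps = read_peaks(write(tmp_path, "p.bed", "chr1\t50\t60\nchr1\t5\t15\n"), "m")
        assert ps.intervals == [("chr1", 5, 15), ("chr1", 50, 60)]

    def test_narrowpeak_first_three_columns(self, tmp_path):
        line = "chr1\t10\t90\tpeak1\t100\t.\t5.1\t3.2\t2.0\t40\n"
        ps = read_peaks(write(tmp_path, "p.narrowPeak", line), "m")
        assert ps.intervals == [("chr1", 10, 90)]

    def test_empty_file_allowed(self, tmp_path):
        ps = read_peaks(write(tmp_path, "p.bed", ""), "m")
        assert len(ps) == 0 and not ps.overlaps("chr1", 0, 100)

    def test_overlap_with_nested_intervals(self):
        # a long interval early in sort order must still be found
        ps = PeakSet("m", [("chr1", 0, 1000), ("chr1", 10, 20)])
        assert ps.overlaps("chr1", 900, 950)


class TestRegionCounts:
    def test_header_and_counts(self, tmp_path):
        rc = read_region_counts(write(tmp_path, "c.tsv", "#total_mapped=1000000\nr1\t50\n"))
        assert rc.counts == {"r1": 50.0} and rc.total_mapped == 1_000_000

    def test_negative_count_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_region_counts(write(tmp_path, "c.tsv", "#total_mapped=10\nr1\t-3\n"))

    def test_duplicate_id_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_region_counts(
                write(tmp_path, "c.tsv", "#total_mapped=10\nr1\t1\nr1\t2\n")
            )

    def test_missing_header_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_region_counts(write(tmp_path, "c.tsv", "r1\t1\n"))

    def test_total_smaller_than_count_rejected(self):
        with pytest.raises(ValueError):
            RegionReadCounts("t", {"r1": 100.0}, 10)


class TestFeatureMatrixIO:
    def make(self):
        return FeatureMatrix(
            ["r1", "r2"],
            ["fa", "fb"],
            np.array([[0.1, 2.0], [3.5, -1.0]]),
            {"r1": "positive", "r2": "negative"},
            {"fa": "I", "fb": "II"},
        )

    def test_roundtrip_identity(self, tmp_path):
        m = self.make()
        path = tmp_path / "fm.tsv"
        write_feature_matrix(m, path)
        assert read_feature_matrix(path) == m

    def test_zero_feature_matrix(self, tmp_path):
        m = FeatureMatrix(
            ["r1"], [], np.empty((1, 0)), {"r1": "positive"}, {}
        )
        path = tmp_path / "fm.tsv"
        write_feature_matrix(m, path)
        m2 = read_feature_matrix(path)
        assert m2.n_features == 0 and m2.labels == m.labels

    def test_tab_in_feature_name_rejected(self, tmp_path):
        m = FeatureMatrix(
            ["r1"], ["a\tb"], np.zeros((1, 1)), {"r1": "positive"}, {"a\tb": "I"}
        )
        with pytest.raises(ValueError):
            write_feature_matrix(m, tmp_path / "fm.tsv")

    def test_duplicate_feature_names_rejected(self):
        with pytest.raises(ValueError):
            FeatureMatrix(
                ["r1"], ["f", "f"], np.zeros((1, 2)), {"r1": "positive"},
                {"f": "I"},
            )

    def test_concat_region_mismatch_rejected(self):
        m = self.make()
        other = FeatureMatrix(
            ["r1", "r3"], ["fc"], np.zeros((2, 1)),
            {"r1": "positive", "r3": "negative"}, {"fc": "I"},
        )
        with pytest.raises(ValueError):
            FeatureMatrix.concat([m, other])
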