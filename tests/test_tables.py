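"""Count/metadata I/O, filtering, and winsorization."""
import numpy as np
import pandas as pd
import pytest

from clrda import (
    CountTable,
    ValidationError,
    filter_table,
    read_counts,
    read_metadata,
    winsorize,
    write_counts,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCounts:
    def test_round_trip_identity(self, tmp_path, small_table):
        path = tmp_path / "counts.tsv"
        write_counts(small_table, path)
        back = read_counts(path)
        assert back.taxon_ids == small_table.taxon_ids
        assert back.sample_ids == small_table.sample_ids
        np.testing.assert_array_equal(back.counts, small_table.counts)

    def test_orientation_symmetry(self, tmp_path, small_table):
        path = tmp_path / "tr.tsv"
        small_table.to_dataframe().T.to_csv(path, sep="\t")
        back = read_counts(path, orientation="samples_rows")
        np.testing.assert_array_equal(back.counts, small_table.counts)
        assert back.taxon_ids == small_table.taxon_ids

    def test_negative_cell_rejected(self, tmp_path):
        p = _write(tmp_path, "bad.tsv", "id\ts1\ts2\ntA\t1\t-1\n")
        with pytest.raises(ValidationError, match="negative"):
            read_counts(p)

    def test_non_numeric_rejected(self, tmp_path):
        p = _write(tmp_path, "bad.tsv", "id\ts1\ntA\tx\n")
        with pytest.raises(ValidationError):
            read_counts(p)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            CountTable(np.ones((2, 1), dtype=int), ["t", "t"], ["s"])

    def test_library_sizes_are_column_sums(self, small_table):
        np.testing.assert_array_equal(
            small_table.library_sizes, small_table.counts.sum(axis=0)
        )


class TestReadMetadata:
    def test_binary_covariate(self, tmp_path):
        p = _write(tmp_path, "md.tsv", "sample\tcase\ns1\t0\ns2\t1\ns3\t1\n")
        sf = read_metadata(p, var="case")
        assert set(np.unique(sf.u)) == {0.0, 1.0}

    def test_categorical_adjuster_expanded(self, tmp_path):
        rows = "\n".join(f"s{i}\t{i % 2}\t{grp}" for i, grp in
                         enumerate(["a", "b", "c", "a", "b", "c"]))
        p = _write(tmp_path, "md.tsv", "sample\tcase\tsite\n" + rows + "\n")
        sf = read_metadata(p, var="case", adjust=("site",))
        assert sf.d == 2  # 3 levels -> 2 indicators, reference dropped

    def test_restricted_to_count_samples(self, tmp_path):
        p = _write(tmp_path, "md.tsv", "sample\tcase\ns1\t0\ns9\t1\ns2\t1\n")
        sf = read_metadata(p, var="case", sample_ids=["s2", "s1"])
        assert sf.sample_ids == ["s2", "s1"]

    def test_missing_column_raises(self, tmp_path):
        p = _write(tmp_path, "md.tsv", "sample\tcase\ns1\t0\n")
        with pytest.raises(ValidationError, match="nope"):
            read_metadata(p, var="nope")

    def test_no_overlap_raises(self, tmp_path):
        p = _write(tmp_path, "md.tsv", "sample\tcase\ns1\t0\n")
        with pytest.raises(ValidationError, match="overlap"):
            read_metadata(p, var="case", sample_ids=["zz"])

    def test_degenerate_grouping_warns(self, tmp_path):
        p = _write(tmp_path, "md.tsv",
                   "sample\tcase\tsubj\ns1\t0\ta\ns2\t1\tb\ns3\t0\tc\n")
        with pytest.warns(UserWarning, match="one subject per sample"):
            read_metadata(p, var="case", group="subj")


class TestFilter:
    def test_library_size_rule(self):
        libs = [500, 1500, 2000, 900, 3000]
        ct = CountTable(np.array([libs]), ["t1"], [f"s{i}" for i in range(5)])
        out, report = filter_table(ct, min_lib=1000, min_prev=0.0)
        assert out.n == 3
        assert report.dropped_samples == ["s0", "s3"]

    def test_prevalence_rule_drops_absent_taxon(self):
        counts = np.array([[0, 0, 0], [5, 5, 5]])
        ct = CountTable(counts, ["absent", "there"], ["a", "b", "c"])
        out, report = filter_table(ct, min_lib=0, min_prev=0.1)
        assert out.taxon_ids == ["there"]
        assert report.dropped_taxa == ["absent"]

    def test_zero_thresholds_identity(self, small_table):
        out, _ = filter_table(small_table, min_lib=0, min_prev=0.0)
        np.testing.assert_array_equal(out.counts, small_table.counts)

    def test_all_samples_removed_raises(self, small_table):
        with pytest.raises(ValidationError):
            filter_table(small_table, min_lib=10**9)

    def test_idempotent_on_simulated_data(self, s0_dataset):
        once, _ = filter_table(s0_dataset.counts)
        twice, _ = filter_table(once)
        assert once.taxon_ids == twice.taxon_ids
        assert once.sample_ids == twice.sample_ids
        np.testing.assert_array_equal(once.counts, twice.counts)


class TestWinsorize:
    def test_q1_identity(self, small_table):
        out = winsorize(small_table, q=1.0)
        np.testing.assert_array_equal(out.counts, small_table.counts)

    def test_outlier_capped_at_quantile(self):
        # 99 samples at proportion 0.01, one at 0.5; the 0.97 quantile of the
        # 100 proportions is 0.01, so the outlier count collapses to it
        counts = np.vstack([
            np.r_[np.full(99, 10), 500],
            np.r_[np.full(99, 990), 500],
        ])
        ct = CountTable(counts, ["hot", "rest"], [f"s{i}" for i in range(100)])
        props = counts[0] / counts.sum(axis=0)
        expected = np.quantile(props, 0.97)
        out = winsorize(ct, q=0.97)
        assert out.counts[0, -1] == round(expected * 1000)
        np.testing.assert_array_equal(out.counts[0, :99], counts[0, :99])

    def test_all_equal_unchanged(self):
        ct = CountTable(np.full((2, 5), 7), ["a", "b"], list("vwxyz"))
        out = winsorize(ct, q=0.97)
        np.testing.assert_array_equal(out.counts, ct.counts)

    def test_never_increases_counts(self, s0_dataset):
        out = winsorize(s0_dataset.counts, q=0.97)
        assert (out.counts <= s0_dataset.counts.counts).all()
        assert out.sample_ids == s0_dataset.counts.sample_ids

    @pytest.mark.parametrize("q", [0.0, -0.5, 1.5])
    def test_bad_quantile(self, small_table, q):
        with pytest.raises(ValueError):
            winsorize(small_table, q=q)
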