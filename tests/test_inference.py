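"""Test statistics, p-values, BH adjustment, and the fixed-effects pipeline."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from clrda import (
    CountTable,
    RunConfig,
    SampleFrame,
    bh_adjust,
    build_design,
    clr_transform,
    debias,
    export_plot_data,
    fit_all_taxa,
    p_values,
    run_fixed,
)
from clrda.inference import test_statistics as compute_statistics


class TestStatistics:
    def test_zero_effect_zero_stat(self, binary_frame):
        di = build_design(binary_frame)
        T, df = compute_statistics(np.zeros(3), np.ones(3), di)
        np.testing.assert_array_equal(T, 0.0)
        assert df == di.df

    def test_linearity_in_effect(self, binary_frame):
        di = build_design(binary_frame)
        T1, _ = compute_statistics(np.array([0.5]), np.array([2.0]), di)
        T2, _ = compute_statistics(np.array([1.0]), np.array([2.0]), di)
        assert T2[0] == pytest.approx(2 * T1[0])

    def test_matches_ols_t_on_shifted_response(self, rng):
        # absorbing the bias into the response reproduces the classical t-stat
        n, m = 60, 30
        ids = [f"s{i}" for i in range(n)]
        u = rng.binomial(1, 0.5, n).astype(float)
        sf = SampleFrame(ids, u)
        di = build_design(sf)
        W = clr_transform(rng.uniform(0.5, 20, (m, n)))
        fit = fit_all_taxa(W, di)
        alpha_hat, est = debias(fit, di)
        T, _ = compute_statistics(alpha_hat, fit.sigma2_hat, di)
        for i in range(0, m, 7):
            shifted = W.W[i] + u * est.bias
            t_classic = sm.OLS(shifted, di.Z).fit().tvalues[0]
            assert abs(T[i] - t_classic) < 1e-8

    def test_degenerate_variance_flagged(self, binary_frame):
        di = build_design(binary_frame)
        with pytest.warns(UserWarning, match="zero residual variance"):
            T, _ = compute_statistics(np.array([1.0]), np.array([0.0]), di)
        assert np.isinf(T[0])
        assert p_values(T, di.df)[0] == 0.0


class TestPValues:
    def test_t_zero_gives_one(self):
        assert p_values(np.array([0.0]), 10)[0] == 1.0

    def test_quantile_oracle_df28(self):
        T = stats.t.ppf(0.975, 28)
        assert p_values(np.array([T]), 28)[0] == pytest.approx(0.05)

    def test_large_df_normal_limit(self):
        p = p_values(np.array([1.96]), 10**6)[0]
        assert p == pytest.approx(2 * stats.norm.cdf(-1.96), abs=1e-5)


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_up_hand_computation(self):
        padj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(padj, 0.04)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        padj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()
        assert (padj >= p - 1e-12).all() and (padj <= 1).all()

    @pytest.mark.parametrize("q", [0.01, 0.05, 0.2])
    def test_rejection_set_matches_fdp_threshold_scan(self, rng, q):
        # BH at level q equals the smallest statistic threshold t* with
        # estimated FDP(t) = m * 2F(-t) / #{|T_i| > t} <= q
        m, df = 300, 50
        T = np.r_[rng.standard_t(df, 260), rng.normal(4, 1, 40)]
        p = 2 * stats.t.cdf(-np.abs(T), df)
        bh_reject = bh_adjust(p) <= q
        ts = np.sort(np.abs(T))
        best = None
        for t in ts:
            n_exceed = (np.abs(T) > t - 1e-12).sum()
            fdp = m * 2 * stats.t.cdf(-(t - 1e-12), df) / max(n_exceed, 1)
            if fdp <= q:
                best = t - 1e-12
                break
        scan_reject = (np.abs(T) > best) if best is not None else np.zeros(m, bool)
        np.testing.assert_array_equal(bh_reject, scan_reject)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestPipeline:
    def test_deterministic(self, s0_dataset):
        cfg = RunConfig()
        r1 = run_fixed(s0_dataset.counts, s0_dataset.samples, cfg)
        r2 = run_fixed(s0_dataset.counts, s0_dataset.samples, cfg)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.bias.bias == r2.bias.bias

    def test_sorted_by_p_with_na_last(self, s0_dataset):
        t = run_fixed(s0_dataset.counts, s0_dataset.samples).table
        pv = t["pvalue"].to_numpy()
        tested = pv[~np.isnan(pv)]
        assert (np.diff(tested) >= 0).all()
        assert t["status"].iloc[-1] == "low_prevalence" or not np.isnan(pv[-1])

    def test_filtered_taxa_reported_with_na(self, s0_dataset):
        t = run_fixed(s0_dataset.counts, s0_dataset.samples).table
        assert set(t["taxon"]) == set(s0_dataset.counts.taxon_ids)
        na_rows = t[t["status"] == "low_prevalence"]
        if len(na_rows):
            assert na_rows["pvalue"].isna().all()
            assert (~na_rows["reject"]).all()

    def test_invariants_of_result_table(self, s0_dataset):
        cfg = RunConfig(fdr_level=0.1)
        t = run_fixed(s0_dataset.counts, s0_dataset.samples, cfg).table
        tested = t[t["status"] == "tested"]
        assert ((tested["pvalue"] >= 0) & (tested["pvalue"] <= 1)).all()
        assert (tested["padj"] >= tested["pvalue"] - 1e-12).all()
        np.testing.assert_array_equal(tested["reject"], tested["padj"] <= 0.1)
        np.testing.assert_allclose(tested["stat"], tested["alpha_debiased"] / tested["se"])

    def test_scale_invariance_zero_free(self, rng):
        # rescaling one sample's counts must not change any p-value
        m, n = 80, 40
        counts = rng.integers(1, 200, (m, n))
        ids = [f"s{i}" for i in range(n)]
        u = np.tile([0.0, 1.0], n // 2)
        sf = SampleFrame(ids, u)
        cfg = RunConfig(min_lib=0, min_prev=0.0, zero="pseudo")
        ct1 = CountTable(counts, [f"t{i}" for i in range(m)], ids)
        scaled = counts.copy()
        scaled[:, 3] *= 7
        ct2 = CountTable(scaled, [f"t{i}" for i in range(m)], ids)
        t1 = run_fixed(ct1, sf, cfg).table
        t2 = run_fixed(ct2, sf, cfg).table
        # tiny jitter from the finite KDE-mode refinement tolerance is allowed
        np.testing.assert_allclose(t1["pvalue"], t2["pvalue"], rtol=1e-5)


class TestPlotData:
    def test_constant_offset_between_effect_columns(self, s0_dataset):
        res = run_fixed(s0_dataset.counts, s0_dataset.samples)
        data = export_plot_data(res)
        diff = data["alpha_debiased"] - data["alpha_raw"]
        np.testing.assert_allclose(diff, res.bias.bias)
        assert len(data) == (res.table["status"] == "tested").sum()
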