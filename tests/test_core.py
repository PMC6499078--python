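"""SUMA component estimation: summaries, pairwise stats, the two OLS fits,
component solving, and end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sumaerr as s
from sumaerr.core import decompose_table, pair_summary


def brute_force_pairs(values):
    """Independent oracle: two-pass covariance in an explicit double loop."""
    n, k = values.shape
    rows = []
    means = values.mean(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            di = values[i] - means[i]
            dj = values[j] - means[j]
            rows.append((i, j, float(di @ dj) / (k - 1), means[i] * means[j]))
    return pd.DataFrame(rows, columns=["i", "j", "c", "zz"])


class TestSummaries:
    def test_constant_row(self):
        t = s.EnsembleTable(np.array(["a", "b"], dtype=object), np.array([[5.0, 5, 5, 5], [1, 2, 3, 4]]))
        out = s.summarize_predictions(t)
        assert out.loc[0, "z"] == 5 and out.loc[0, "v"] == 0 and out.loc[0, "z2"] == 25

    def test_textbook_sample_variance(self):
        t = s.EnsembleTable(np.array(["a", "b"], dtype=object), np.array([[1.0, 2, 3, 4], [0, 0, 0, 1]]))
        out = s.summarize_predictions(t)
        assert out.loc[0, "z"] == 2.5
        assert out.loc[0, "v"] == pytest.approx(5 / 3)
        assert out.loc[0, "z2"] == 2.5**2

    def test_weighted_mean_option(self):
        t = s.EnsembleTable(np.array(["a", "b"], dtype=object), np.array([[1.0, 3.0], [2.0, 2.0]]))
        out = s.summarize_predictions(t, weights=np.array([3.0, 1.0]))
        assert out.loc[0, "z"] == pytest.approx(1.5)  # (3*1 + 1*3)/4
        assert out.loc[0, "v"] == pytest.approx(2.0)  # variance stays unweighted
        pairs = s.pairwise_stats(t, weights=np.array([3.0, 1.0]))
        assert pairs.loc[0, "zz"] == pytest.approx(1.5 * 2.0)
        with pytest.raises(ValueError, match="weights"):
            s.summarize_predictions(t, weights=np.array([-1.0, 1.0]))

    def test_error_free_simulation_gives_zero_variance(self):
        spec = s.SimulationSpec(n_pred=30, n_ens=10, sigma_sm2=0, sigma_m2=0, sigma_sa2=0, sigma_a2=0, seed=1)
        table, _, _ = s.simulate(spec)
        # zero up to accumulation round-off: X equals Z bit-for-bit, but the
        # row mean of k identical doubles need not
        assert (s.summarize_predictions(table)["v"] < 1e-20).all()


class TestPairwise:
    def test_identical_rows_covariance_equals_variance(self, tiny_table):
        pairs = s.pairwise_stats(tiny_table)
        row = pairs[(pairs["i"] == 0) & (pairs["j"] == 1)].iloc[0]
        assert row["c"] == pytest.approx(5 / 3)
        assert row["zz"] == pytest.approx(6.25)

    def test_anticorrelated_rows(self, tiny_table):
        pairs = s.pairwise_stats(tiny_table)
        row = pairs[(pairs["i"] == 0) & (pairs["j"] == 2)].iloc[0]
        assert row["c"] == pytest.approx(-10 / 3)

    def test_pair_count_is_n_choose_2(self):
        rng = np.random.default_rng(0)
        t = s.EnsembleTable(np.array([f"p{i}" for i in range(80)], dtype=object), rng.normal(size=(80, 6)))
        assert len(s.pairwise_stats(t)) == 80 * 79 // 2

    def test_blockwise_matches_brute_force(self):
        rng = np.random.default_rng(5)
        t = s.EnsembleTable(
            np.array([f"p{i}" for i in range(60)], dtype=object), rng.lognormal(3, 0.5, size=(60, 12))
        )
        got = s.pairwise_stats(t, block_size=7)  # force many partial blocks
        want = brute_force_pairs(t.values)
        np.testing.assert_allclose(got["c"], want["c"], rtol=1e-10)
        np.testing.assert_allclose(got["zz"], want["zz"], rtol=1e-10)
        assert got[["i", "j"]].apply(tuple, axis=1).is_unique

    def test_single_prediction_rejected(self):
        t = s.EnsembleTable(np.array(["a"], dtype=object), np.ones((1, 3)))
        with pytest.raises(ValueError, match="at least 2"):
            s.pairwise_stats(t)


class TestRegressions:
    def test_flat_response(self):
        pairs = pd.DataFrame({"i": [0, 0, 1], "j": [1, 2, 2], "c": [0.5, 0.5, 0.5], "zz": [1.0, 2.0, 3.0]})
        fit = s.fit_shared_regression(pairs)
        assert fit.intercept == pytest.approx(0.5)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_regressor_rejected(self):
        pairs = pd.DataFrame({"i": [0, 0, 1], "j": [1, 2, 2], "c": [0.5, 0.6, 0.7], "zz": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="degenerate"):
            s.fit_shared_regression(pairs)

    def test_zero_variance_table_fits_zero(self):
        summaries = pd.DataFrame({"prediction_id": list("abcd"), "z": [1, 2, 3, 4], "v": [0.0] * 4, "z2": [1, 4, 9, 16]})
        fit = s.fit_unshared_regression(summaries)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_shared_slope_recovers_generative_variance(self, paper_regime):
        table, _, _ = paper_regime
        fit = s.fit_shared_regression(s.pairwise_stats(table))
        assert fit.slope == pytest.approx(0.0003, rel=0.5)
        assert fit.slope_p < 1e-4

    def test_unshared_slope_recovers_total_relative_variance(self, paper_regime):
        table, _, _ = paper_regime
        fit = s.fit_unshared_regression(s.summarize_predictions(table))
        assert fit.slope == pytest.approx((1.0003 * 1.0075) - 1, rel=0.1)


class TestSolveComponents:
    @staticmethod
    def _fit(intercept, slope):
        return s.RegressionFit(intercept, slope, 1e-3, 1e-6, 0.0, 0.0, 100)

    def test_printed_worked_example(self):
        comp = s.solve_components(self._fit(-0.2516, 0.00029), self._fit(-5.39406, 0.0078))
        assert round(comp.sigma_m2, 5) == 0.00751
        assert comp.sigma_sa2 == 0 and comp.sigma_a2 == 0
        assert comp.truncated["sigma_sa2"] and comp.truncated["sigma_a2"]

    def test_no_sharing_passes_slope_through(self):
        comp = s.solve_components(self._fit(0.0, 0.0), self._fit(0.0, 0.042))
        assert comp.sigma_m2 == pytest.approx(0.042)

    def test_multiplicative_product_relation(self):
        comp = s.solve_components(self._fit(0.0, 0.1), self._fit(0.0, 0.21))
        assert comp.sigma_m2 == pytest.approx(0.1)

    def test_impossible_total_variance_rejected(self):
        with pytest.raises(ValueError, match="<= -1"):
            s.solve_components(self._fit(0, 0.1), self._fit(0, -1.5))

    @settings(max_examples=200, derandomize=True)
    @given(
        sm2=st.floats(0, 5, allow_nan=False),
        m2=st.floats(0, 5, allow_nan=False),
        sa2=st.floats(0, 10, allow_nan=False),
        a2=st.floats(0, 10, allow_nan=False),
    )
    def test_solving_inverts_the_generative_slopes(self, sm2, m2, sa2, a2):
        """Analytic slopes in, the same components out, to machine precision."""
        shared = self._fit(sa2, sm2)
        unshared = self._fit(sa2 + a2, (1 + sm2) * (1 + m2) - 1)
        comp = s.solve_components(shared, unshared)
        assert comp.sigma_sm2 == pytest.approx(sm2, rel=1e-12, abs=1e-12)
        assert comp.sigma_m2 == pytest.approx(m2, rel=1e-9, abs=1e-9)
        assert comp.sigma_sa2 == pytest.approx(sa2, rel=1e-12, abs=1e-12)
        assert comp.sigma_a2 == pytest.approx(a2, rel=1e-12, abs=1e-10)
        assert not any(comp.truncated.values())

    def test_truncation_flags_set_iff_raw_negative(self):
        comp = s.solve_components(self._fit(-0.1, 0.01), self._fit(0.2, 0.02))
        assert comp.truncated == {
            "sigma_sm2": False, "sigma_sa2": True, "sigma_m2": False, "sigma_a2": False,
        }
        assert comp.sigma_a2 == pytest.approx(0.2)  # sa2 truncated before differencing


class TestPipelines:
    def test_error_free_table_yields_all_zero_components(self):
        spec = s.SimulationSpec(n_pred=40, n_ens=8, sigma_sm2=0, sigma_m2=0, sigma_sa2=0, sigma_a2=0, seed=2)
        table, meta, _ = s.simulate(spec)
        res = s.run_suma(table, meta, s.SampleSpec(sample_size=40, n_repeats=1, seed=0))
        assert res.components.as_series().abs().max() < 1e-20

    def test_repeat_spread_small_relative_to_mean(self, paper_regime):
        table, meta, _ = paper_regime
        res = s.run_suma(table, meta, s.SampleSpec(sample_size=300, n_repeats=5, seed=3))
        spread = res.spread()
        for comp in ("sigma_sm2", "sigma_m2"):
            assert spread.loc["std", comp] < spread.loc["mean", comp]

    def test_single_stratum_equals_run_suma(self, paper_regime):
        table, meta, _ = paper_regime
        meta = meta.copy()
        meta["one"] = "all"
        spec = s.SampleSpec(sample_size=200, n_repeats=1, seed=17)
        direct = s.run_suma(table, meta, spec).components
        strat = s.stratified_suma(table, meta, "one", spec)["all"]["components"]
        assert strat.as_series().equals(direct.as_series())

    def test_stratified_recovers_generative_period_ordering(self, study):
        table, meta, _ = study
        # near-whole strata: the planted high-error region adds leverage
        # noise, so small per-stratum samples can scramble the ordering
        out = s.stratified_suma(table, meta, "period", s.SampleSpec(sample_size=1000, n_repeats=1, seed=5))
        sm = {k: v["components"].sigma_sm2 for k, v in out.items()}
        assert sm["1992-2000"] > sm["2001-2004"]
        assert sm["1992-2000"] > sm["2005-2012"]
        for v in out.values():
            assert set(v["pair_summary"]) >= {"min_covariance", "max_covariance", "median_covariance"}

    def test_pair_summary_matches_direct_quantiles(self, tiny_table):
        pairs = s.pairwise_stats(tiny_table)
        ps = pair_summary(pairs)
        assert ps["min_covariance"] == pairs["c"].min()
        assert ps["median_product_mean"] == pairs["zz"].median()

    def test_decompose_table_matches_manual_composition(self, paper_regime):
        table, _, _ = paper_regime
        manual = s.solve_components(
            s.fit_shared_regression(s.pairwise_stats(table)),
            s.fit_unshared_regression(s.summarize_predictions(table)),
        )
        assert decompose_table(table).as_series().equals(manual.as_series())
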