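"""Plot aggregation, habitat comparison and microclimate models."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from understorey import habitatstats as hs
from understorey import synthdata as sd


def enumeration_rank_sum_p(x, y):
    """Independent oracle: exact two-sided rank-sum p by enumerating all
    C(n, n1) assignments of the pooled (tie-free) values."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(a, b):
        return sum(1 for i in a for j in b if i > j)

    u_obs = u_stat(x, y)
    us = []
    idx = range(len(pooled))
    for sel in combinations(idx, n1):
        sel_set = set(sel)
        a = [pooled[i] for i in sel]
        b = [pooled[i] for i in idx if i not in sel_set]
        us.append(u_stat(a, b))
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestAggregateToPlot:
    def _samples(self):
        return pd.DataFrame({
            "plot_id": ["p1"] * 5,
            "metric": ["NDVI_down"] * 5,
            "mean": [1.0, 2.0, 3.0, 4.0, 5.0],
            "excluded": [False] * 5,
        })

    def test_mean_and_max(self):
        s = self._samples()
        assert hs.aggregate_to_plot(s, "mean").loc["p1", "NDVI_down"] == 3.0
        assert hs.aggregate_to_plot(s, "max").loc["p1", "NDVI_down"] == 5.0
        assert hs.aggregate_to_plot(s, "min").loc["p1", "NDVI_down"] == 1.0

    def test_excluded_samples_skipped(self):
        s = self._samples()
        s.loc[4, "excluded"] = True
        assert hs.aggregate_to_plot(s, "max").loc["p1", "NDVI_down"] == 4.0

    def test_all_excluded_gives_missing(self):
        s = self._samples()
        s["excluded"] = True
        agg = hs.aggregate_to_plot(s, "mean")
        assert "p1" in agg.index
        assert agg.loc["p1"].isna().all()

    def test_unknown_statistic(self):
        with pytest.raises(ValueError):
            hs.aggregate_to_plot(self._samples(), "median-of-medians")


class TestTreelessDefaults:
    def test_grassland_receives_defaults(self):
        df = pd.DataFrame({
            "plot_id": ["a", "b"],
            "habitat": ["grassland", "forest"],
            "lai": [np.nan, 3.0], "fcover": [np.nan, 80.0],
            "ndvi_up": [np.nan, 0.6],
        })
        out = hs.assign_treeless_defaults(df)
        assert tuple(out.loc[0, ["lai", "fcover", "ndvi_up"]]) == (0.0, 0.0, -1.0)
        assert tuple(out.loc[1, ["lai", "fcover", "ndvi_up"]]) == (3.0, 80.0, 0.6)

    def test_measured_grassland_canopy_warns_but_overrides(self):
        df = pd.DataFrame({
            "plot_id": ["a"], "habitat": ["grassland"],
            "lai": [1.2], "fcover": [15.0], "ndvi_up": [0.1],
        })
        with pytest.warns(UserWarning):
            out = hs.assign_treeless_defaults(df)
        assert out.loc[0, "lai"] == 0.0


class TestPairwiseWilcoxon:
    def test_separated_triples_exact_p(self):
        m = hs.pairwise_wilcoxon({"a": [1, 2, 3], "b": [4, 5, 6]},
                                 adjustment="none")
        assert m.loc["a", "b"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_adjusted_to_one(self):
        m = hs.pairwise_wilcoxon({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert m.loc["a", "b"] == 1.0

    def test_bonferroni_triples_raw_p_with_three_groups(self):
        g = {"a": [1, 2, 3, 4], "b": [10, 11, 12, 13], "c": [5.5, 6.5, 7.5, 8.5]}
        raw = hs.pairwise_wilcoxon(g, adjustment="none")
        adj = hs.pairwise_wilcoxon(g)
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            assert adj.loc[x, y] == pytest.approx(min(1.0, 3 * raw.loc[x, y]))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="tiny"):
            hs.pairwise_wilcoxon({"tiny": [1.0], "other": [1, 2, 3]})

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_for_small_samples(self, data):
        """Implementation equals exhaustive enumeration for all tie-free
        two-group inputs with combined n <= 10."""
        n1 = data.draw(st.integers(2, 5))
        n2 = data.draw(st.integers(2, min(5, 10 - n1)))
        values = data.draw(st.lists(st.integers(-50, 50), min_size=n1 + n2,
                                    max_size=n1 + n2, unique=True))
        x, y = values[:n1], values[n1:]
        m = hs.pairwise_wilcoxon({"x": x, "y": y}, adjustment="none")
        assert m.loc["x", "y"] == pytest.approx(enumeration_rank_sum_p(x, y),
                                                abs=1e-12)


class TestFitLm:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = hs.fit_lm(2 + 3 * x, x)
        assert fit.intercept == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficient == pytest.approx(3.0, abs=1e-10)
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_zero_slope(self):
        fit = hs.fit_lm(np.full(10, 5.0), np.arange(10.0))
        assert fit.coefficient == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            hs.fit_lm(np.arange(5.0), np.ones(5))

    def test_ci_coverage_under_simulation(self):
        """95% CIs cover the true slope in >= 90% of seeded replicates of
        the Thermal_ground ~ LAI relation (truth 27.4 - 1.19 LAI)."""
        covered = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 6, 34)
            y = 27.4 - 1.19 * x + rng.normal(0, 0.5, 34)
            lo, hi = hs.fit_lm(y, x).conf_int["coefficient"]
            covered += lo <= -1.19 <= hi
        assert covered / reps >= 0.90


class TestFitGam:
    def test_linear_data_collapses_to_line(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 40)
        y = 2 + 3 * x + rng.normal(0, 0.3, 40)
        gam = hs.fit_gam(y, x)
        lm = hs.fit_lm(y, x)
        assert gam.coefficient == pytest.approx(1.0, abs=0.1)  # edf
        assert gam.adjusted_r2 == pytest.approx(lm.adjusted_r2, abs=0.01)

    def test_curvature_beats_linear_model(self):
        rng = np.random.default_rng(3)
        x = np.linspace(-1, 1, 40)
        y = x ** 2 + rng.normal(0, 0.03, 40)
        assert hs.fit_gam(y, x).adjusted_r2 > hs.fit_lm(y, x).adjusted_r2

    def test_constant_response(self):
        gam = hs.fit_gam(np.ones(20), np.linspace(0, 1, 20))
        assert gam.coefficient <= 1.1
        assert gam.adjusted_r2 <= 0.0 + 1e-9

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            hs.fit_gam(np.arange(5.0), np.arange(5.0))

    def test_prediction_follows_smooth(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 2 * np.pi, 60)
        y = np.sin(x) + rng.normal(0, 0.05, 60)
        gam = hs.fit_gam(y, x)
        assert np.corrcoef(gam.predict(x), y)[0, 1] > 0.98


class TestSelectModel:
    def _fit(self, kind, r2):
        return hs.ModelFit(kind=kind, response="y", predictor="x",
                           intercept=0.0, coefficient=1.0, adjusted_r2=r2)

    def test_tie_goes_to_linear(self):
        assert hs.select_model(self._fit("LM", 0.51), self._fit("GAM", 0.51)).kind == "LM"
        assert hs.select_model(self._fit("LM", 0.512), self._fit("GAM", 0.509)).kind == "LM"

    def test_clear_winner(self):
        assert hs.select_model(self._fit("LM", 0.10), self._fit("GAM", 0.39)).kind == "GAM"
        assert hs.select_model(self._fit("LM", 0.30), self._fit("GAM", 0.20)).kind == "LM"

    def test_mismatched_variables_rejected(self):
        other = hs.ModelFit(kind="GAM", response="y", predictor="z",
                            intercept=0, coefficient=1, adjusted_r2=0.5)
        with pytest.raises(ValueError):
            hs.select_model(self._fit("LM", 0.5), other)

    def test_pure_function(self):
        a, b = self._fit("LM", 0.3), self._fit("GAM", 0.4)
        assert hs.select_model(a, b) is hs.select_model(a, b)


class TestInteractionModel:
    COEFFS = (2.074357, 0.155010, 0.887836, -0.007211)

    def _noiseless_fit(self, seed=0):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0, 100, 34)
        t = rng.uniform(21, 29, 34)
        b0, bs, bt, bi = self.COEFFS
        y = b0 + bs * f + bt * t + bi * f * t
        return hs.fit_interaction(y, f, t)

    def test_noiseless_recovery_to_machine_precision(self):
        fit = self._noiseless_fit()
        for got, want in zip((fit.b0, fit.b_struct, fit.b_T, fit.b_interact),
                             self.COEFFS):
            assert got == pytest.approx(want, abs=1e-9)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0, 100, 30)
        t = rng.uniform(21, 29, 30)
        y = 2 + 0.1 * f + 0.9 * t - 0.006 * f * t + rng.normal(0, 1, 30)
        fit1 = hs.fit_interaction(y, f, t)
        perm = rng.permutation(30)
        fit2 = hs.fit_interaction(y[perm], f[perm], t[perm])
        assert fit1.b_interact == pytest.approx(fit2.b_interact, abs=1e-10)

    def test_null_interaction_rarely_significant(self):
        """Type-I error control: with zero interaction truth the
        interaction term tests non-significant in >= 90% of replicates."""
        hits = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            f = rng.uniform(0, 100, 34)
            t = rng.uniform(21, 29, 34)
            y = 5 + 0.05 * f + 0.8 * t + rng.normal(0, 1.0, 34)
            fit = hs.fit_interaction(y, f, t)
            hits += fit.p_values["interaction"] >= 0.05
        assert hits / reps >= 0.90

    def test_collinear_design_rejected(self):
        f = np.ones(10)
        t = np.linspace(21, 29, 10)
        with pytest.raises(ValueError):
            hs.fit_interaction(t, f, t)

    def test_evaluate_at_tair(self):
        fit = self._noiseless_fit()
        icpt29, slope29 = hs.evaluate_at_tair(fit, 29.0)
        assert slope29 == pytest.approx(0.155010 - 0.007211 * 29, abs=1e-9)
        icpt21, slope21 = fit.evaluate_at_tair(21.0)
        assert icpt21 == pytest.approx(2.074357 + 0.887836 * 21, abs=1e-9)
        assert round(icpt21, 1) == 20.7
        assert round(slope21, 5) == 0.00358

    def test_zero_interaction_slope_independent_of_t(self):
        fit = hs.InteractionFit(b0=1.0, b_struct=-0.06, b_T=0.5,
                                b_interact=0.0, adjusted_r2=0.9)
        assert fit.evaluate_at_tair(21)[1] == fit.evaluate_at_tair(29)[1]


class TestPredictChange:
    def test_canopy_opening_deltas(self):
        fit = hs.ModelFit(kind="LM", response="thermal_ground",
                          predictor="fcover", intercept=27.6,
                          coefficient=-0.06, adjusted_r2=0.51)
        assert hs.predict_change(fit, 20) == pytest.approx(-1.2)
        assert hs.predict_change(fit, 0) == 0.0

    def test_lai_slope(self):
        fit = hs.ModelFit(kind="LM", response="thermal_ground",
                          predictor="lai", intercept=27.4, coefficient=-1.19,
                          adjusted_r2=0.52)
        assert hs.predict_change(fit, 1) == pytest.approx(-1.19)

    def test_smooth_fit_rejected(self):
        fit = hs.ModelFit(kind="GAM", response="y", predictor="x",
                          intercept=0, coefficient=2.0, adjusted_r2=0.5)
        with pytest.raises(ValueError):
            hs.predict_change(fit, 1.0)


class TestPlotDatasetRecovery:
    def test_noiseless_dataset_makes_lm_exact(self):
        """Full-pipeline identity: zero generator noise makes every
        downstream estimate exact."""
        params = sd.PlotSimParams(
            n_plots=34, coefficients=sd.PlotTruth(thermal_model="lai"),
            noise_sd_thermal=0.0, noise_sd_ndvi=0.0, seed=1)
        df = hs.assign_treeless_defaults(sd.gen_plot_dataset(params))
        fit = hs.fit_lm(df.thermal_ground, df.lai)
        assert fit.intercept == pytest.approx(27.4, abs=1e-9)
        assert fit.coefficient == pytest.approx(-1.19, abs=1e-9)
        nd = hs.fit_lm(df.ndvi_down, df.lai)
        assert nd.intercept == pytest.approx(0.57, abs=1e-9)
        assert nd.coefficient == pytest.approx(-0.09, abs=1e-9)

    def test_null_slope_rarely_significant(self):
        """Generator + LM type-I error: with all coefficients zero the
        slope tests non-significant in >= 90% of 100 replicates."""
        truth = sd.PlotTruth(thermal_model="lai", thermal_lai=(25.0, 0.0))
        hits = 0
        for seed in range(100):
            params = sd.PlotSimParams(n_plots=20, coefficients=truth,
                                      noise_sd_thermal=1.0, seed=seed)
            df = hs.assign_treeless_defaults(sd.gen_plot_dataset(params))
            fit = hs.fit_lm(df.thermal_ground, df.lai)
            hits += fit.p_values["coefficient"] >= 0.05
        assert hits / 100 >= 0.90

    def test_grassland_rows_have_empty_canopy_fields(self):
        params = sd.PlotSimParams(n_plots=20, seed=3)
        df = sd.gen_plot_dataset(params)
        grass = df[df.habitat == "grassland"]
        assert len(grass) > 0
        assert grass[["lai", "fcover", "ndvi_up"]].isna().all().all()

    def test_too_few_plots_rejected(self):
        with pytest.raises(ValueError):
            sd.PlotSimParams(n_plots=3)
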