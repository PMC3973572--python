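"""Cohesion models: NB fits with offsets, AICc, space-time autocovariate,
hypothesis comparison, leverage."""

import numpy as np
import pandas as pd
import pytest

from nestmosaic import synthdata
from nestmosaic.cohesion import (
    CohesionModel,
    aicc,
    compare_hypotheses,
    environmental_block_test,
    fit_cohesion,
    leverage_screen,
    spatiotemporal_autocovariate,
    HUMAN_CONTROLS,
)
from nestmosaic.dynamics import build_autocovariate


@pytest.fixture(scope="module")
def sites():
    return synthdata.simulate_nesting_sites(seed=21)


class TestAICc:
    def test_closed_form(self):
        # AIC = 100 with k = 2, n = 10: correction 2*2*3/7
        val = aicc(loglik=-48.0, k=2, n=10)
        assert val == pytest.approx(100.0 + 12.0 / 7.0)

    def test_large_n_limit(self):
        assert aicc(-48.0, 2, 10**7) == pytest.approx(100.0, abs=1e-4)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            aicc(-48.0, 5, 6)


class TestSpatioTemporalAC:
    loc = np.array([[0.0, 0.0], [1.0, 0.0], [4.0, 3.0]])
    dates = ["2012-01-01", "2012-01-21", "2012-03-01"]
    resid = np.array([1.0, -0.5, 2.0])

    def test_constant_residuals(self):
        ac = spatiotemporal_autocovariate(self.loc, self.dates,
                                          [3.0, 3.0, 3.0], 1.0, 10.0)
        assert np.allclose(ac, 3.0)

    def test_infinite_temporal_sd_reduces_to_spatial(self):
        ac = spatiotemporal_autocovariate(self.loc, self.dates, self.resid,
                                          2.0, 1e12)
        spatial = build_autocovariate(self.loc, self.resid, 2.0)
        assert np.allclose(ac, spatial, atol=1e-10)

    def test_three_site_hand_computation(self):
        ss, st = 2.0, 30.0
        days = np.array([0.0, 20.0, 60.0])
        d = np.linalg.norm(self.loc[:, None] - self.loc[None], axis=-1)
        k = (np.exp(-0.5 * (d / ss) ** 2)
             * np.exp(-0.5 * ((days[:, None] - days[None]) / st) ** 2))
        np.fill_diagonal(k, 0.0)
        expected = k @ self.resid / k.sum(axis=1)
        ac = spatiotemporal_autocovariate(self.loc, self.dates, self.resid,
                                          ss, st)
        assert np.allclose(ac, expected, atol=1e-12)

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            spatiotemporal_autocovariate(self.loc[:1], self.dates[:1],
                                         [1.0], 1.0, 1.0)


class TestCohesionFit:
    def test_offset_scaling_shifts_only_intercept(self, sites):
        base = fit_cohesion(sites, "builders_forest")
        scaled = sites.copy()
        scaled["builders_forest"] = scaled["builders_forest"] * 3.0
        shifted = fit_cohesion(scaled, "builders_forest")
        assert shifted.params["const"] == pytest.approx(
            base.params["const"] - np.log(3.0), abs=1e-5)
        for p in base.predictors:
            assert shifted.params[p] == pytest.approx(base.params[p],
                                                      abs=1e-5)

    def test_design_is_standardized(self, sites):
        res = fit_cohesion(sites, "builders_forest")
        X = res.nb.model.exog
        cols = np.asarray(X)[:, 1:]  # skip intercept
        assert np.allclose(cols.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(cols.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_null_structure_gives_flat_slopes(self):
        rng = np.random.default_rng(3)
        n = 120
        df = pd.DataFrame({
            "nest_count": rng.poisson(2.0 * 8.0, n),
            "builders_forest": np.full(n, 8.0),
            "density_suitable_trees": rng.gamma(4, 20, n),
            "fruit_forest_14d": rng.gamma(3, 2, n),
            "fruit_site": rng.gamma(2, 1, n),
            "village_influence": rng.gamma(5, 30, n),
            "human_forest_use": rng.lognormal(1, 0.5, n),
            "rainfall_30d": rng.gamma(4, 30, n),
        })
        df["nest_count"] = df["nest_count"].clip(lower=1)
        res = fit_cohesion(df, "builders_forest")
        assert res.params["const"] == pytest.approx(np.log(2.0), abs=0.1)
        for p in res.predictors:
            assert abs(res.params[p]) < 0.1

    def test_nonpositive_offset_rejected(self, sites):
        bad = sites.copy()
        bad.loc[bad.index[0], "builders_forest"] = 0.0
        with pytest.raises(ValueError):
            fit_cohesion(bad, "builders_forest")


class TestComparison:
    def test_identical_fits_tie(self, sites):
        f = fit_cohesion(sites, "builders_forest")
        comp = compare_hypotheses(f, f)
        assert comp.winner == "tie" and comp.delta == 0.0

    def test_generating_regime_wins(self, sites):
        m1 = CohesionModel(sites, "one_community").fit(ac=None)
        m2 = CohesionModel(sites, "two_communities").fit(ac=None)
        comp = compare_hypotheses(m1, m2)
        assert comp.winner == "two_communities"

    def test_mismatched_n_rejected(self, sites):
        f1 = fit_cohesion(sites, "builders_forest")
        f2 = fit_cohesion(sites.iloc[:-5], "builders_forest")
        with pytest.raises(ValueError):
            compare_hypotheses(f1, f2)


class TestBlockTest:
    def test_df_counts_environmental_predictors(self, sites):
        full = fit_cohesion(sites, "builders_forest")
        null = fit_cohesion(sites, "builders_forest",
                            predictors=HUMAN_CONTROLS)
        chi2, df, p = environmental_block_test(full, null)
        assert df == 4
        assert chi2 == pytest.approx(2 * (full.llf - null.llf), abs=1e-8)
        assert 0.0 <= p <= 1.0

    def test_non_nested_rejected(self, sites):
        full = fit_cohesion(sites, "builders_forest")
        with pytest.raises(ValueError):
            environmental_block_test(full, full)


class TestLeverage:
    def test_balanced_design_flags_nothing(self, sites):
        fit = fit_cohesion(sites, "builders_forest")
        retained, report = leverage_screen(fit)
        assert report["flagged"].sum() <= 2  # at most isolated extremes
        retained_all, _ = leverage_screen(fit, threshold_factor=np.inf)
        assert len(retained_all) == fit.nobs

    def test_extreme_point_flagged(self, sites):
        spiked = sites.copy()
        i = spiked.index[0]
        spiked.loc[i, "fruit_site"] = spiked["fruit_site"].max() * 30
        fit = fit_cohesion(spiked, "builders_forest")
        retained, report = leverage_screen(fit)
        assert report.loc[0, "flagged"]
        assert 0 not in retained
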