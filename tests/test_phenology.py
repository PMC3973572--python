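"""Fruit index construction, power transform, seasonal model, F-tests."""

import numpy as np
import pandas as pd
import pytest

from nestmosaic.phenology import (
    SeasonalFruitModel,
    basal_area_table,
    daily_fruiting_proportion,
    date_angle,
    estimate_power_transform,
    f_test,
    fruit_index,
)


def obs_frame(rows):
    return pd.DataFrame(rows, columns=["forest", "date", "species",
                                       "n_trees", "n_fruiting"])


class TestFruitIndex:
    ba = pd.DataFrame({"species": ["a", "b"], "basal_m2_ha": [2.0, 4.0]})

    def test_single_species_hand_value(self):
        obs = obs_frame([("F", "2012-01-01", "a", 10, 5)])
        out = fruit_index(obs, self.ba, by=("forest", "date"))
        assert out["value"].iloc[0] == pytest.approx(1.0)

    def test_no_fruiting_gives_zero(self):
        obs = obs_frame([("F", "2012-01-01", "a", 10, 0)])
        out = fruit_index(obs, self.ba, by=("forest", "date"))
        assert out["value"].iloc[0] == 0.0

    def test_two_species_hand_sum(self):
        obs = obs_frame([("F", "2012-01-01", "a", 10, 5),
                         ("F", "2012-01-01", "b", 8, 2)])
        out = fruit_index(obs, self.ba, by=("forest", "date"))
        assert out["value"].iloc[0] == pytest.approx(0.5 * 2 + 0.25 * 4)

    def test_species_set_additivity(self):
        obs = obs_frame([("F", "2012-01-01", "a", 10, 5),
                         ("F", "2012-01-01", "b", 8, 2)])
        both = fruit_index(obs, self.ba, by=("forest",))["value"].iloc[0]
        only_a = fruit_index(obs, self.ba, species=["a"],
                             by=("forest",))["value"].iloc[0]
        only_b = fruit_index(obs, self.ba, species=["b"],
                             by=("forest",))["value"].iloc[0]
        assert both == pytest.approx(only_a + only_b)

    def test_missing_basal_area_excluded_with_warning(self):
        obs = obs_frame([("F", "2012-01-01", "a", 10, 5),
                         ("F", "2012-01-01", "zz", 10, 10)])
        with pytest.warns(UserWarning, match="zz"):
            out = fruit_index(obs, self.ba, by=("forest",))
        assert out["value"].iloc[0] == pytest.approx(1.0)

    def test_basal_area_from_dbh(self):
        trees = pd.DataFrame({"species": ["a", "a"], "dbh_cm": [20.0, 40.0]})
        out = basal_area_table(trees, area_ha=2.0)
        expected = (np.pi * 0.1**2 + np.pi * 0.2**2) / 2.0
        assert out["basal_m2_ha"].iloc[0] == pytest.approx(expected)


class TestPowerTransform:
    def test_identity_scale_lambda_near_one(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(300), rng.normal(size=300)])
        y = 10 + 2 * X[:, 1] + rng.normal(0, 1, 300)
        pt = estimate_power_transform(y, X)
        assert abs(pt.lambda_ - 1.0) < 0.35

    def test_lognormal_response_recovers_lambda_zero(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(300), rng.normal(size=300)])
        y = np.exp(1.0 + 0.5 * X[:, 1] + rng.normal(0, 0.4, 300))
        pt = estimate_power_transform(y, X)
        assert abs(pt.lambda_) < 0.15

    def test_profile_is_unimodal_near_optimum(self):
        rng = np.random.default_rng(2)
        X = np.ones((200, 1))
        y = np.exp(rng.normal(2.0, 0.5, 200))
        from nestmosaic.phenology import _boxcox_profile_loglik
        grid = np.linspace(-2, 2, 41)
        ll = np.array([_boxcox_profile_loglik(l, y, X) for l in grid])
        peak = np.argmax(ll)
        assert np.all(np.diff(ll[:peak + 1]) > 0)
        assert np.all(np.diff(ll[peak:]) < 0)

    def test_nonpositive_response_rejected(self):
        with pytest.raises(ValueError):
            estimate_power_transform([1.0, -2.0], np.ones((2, 1)))


def make_series(rng, b_forest=0.9, b_sin=0.3, b_cos=-0.1, noise=0.1,
                year="2012", periods=26):
    dates = pd.date_range(f"{year}-01-05", periods=periods, freq="14D")
    rows = []
    for forest, off in (("Mpelu", 0.0), ("Nkala", b_forest)):
        ang = date_angle(dates)
        mu = 3.0 + off + b_sin * np.sin(ang) + b_cos * np.cos(ang)
        vals = np.exp(mu + rng.normal(0, noise, len(dates)))
        rows.append(pd.DataFrame({"date": dates, "forest": forest,
                                  "value": vals}))
    return pd.concat(rows, ignore_index=True)


class TestSeasonalModel:
    def test_recovers_seasonal_coefficients(self):
        rng = np.random.default_rng(3)
        s = make_series(rng)
        res = SeasonalFruitModel(s, lambda_=0.0).fit()
        assert res.params["sin_date"] == pytest.approx(0.3, abs=0.1)
        assert res.params["forest[Nkala]"] == pytest.approx(0.9, abs=0.12)
        assert res.amplitude == pytest.approx(np.hypot(0.3, 0.1), abs=0.12)

    def test_amplitude_invariant_to_date_origin(self):
        # shifting every date by a constant (within one year, so the
        # day-of-year map stays linear) rotates the sin/cos pair without
        # changing the seasonal amplitude
        rng = np.random.default_rng(4)
        s = make_series(rng, year="2013", periods=20)
        res1 = SeasonalFruitModel(s, lambda_=0.0).fit()
        shifted = s.copy()
        shifted["date"] = shifted["date"] + pd.Timedelta(days=40)
        res2 = SeasonalFruitModel(shifted, lambda_=0.0).fit()
        assert res2.amplitude == pytest.approx(res1.amplitude, abs=1e-8)
        assert res2.phase != pytest.approx(res1.phase, abs=1e-3)

    def test_autocovariate_column_added(self):
        rng = np.random.default_rng(5)
        s = make_series(rng)
        res = SeasonalFruitModel(s, lambda_=0.0).fit(ac_sd_days=20.0)
        assert "ac_term" in res.params.index
        assert res.ac_sd_days == 20.0

    def test_nonpositive_index_rejected(self):
        s = pd.DataFrame({"date": ["2012-01-01"], "forest": ["F"],
                          "value": [0.0]})
        with pytest.raises(ValueError):
            SeasonalFruitModel(s)


class TestFTest:
    def test_identical_models(self):
        rng = np.random.default_rng(6)
        s = make_series(rng)
        m = SeasonalFruitModel(s, lambda_=0.0)
        res = m.fit()
        F, df1, df2, p = f_test(res, res)
        assert F == 0.0 and p == 1.0

    def test_single_regressor_f_equals_t_squared(self):
        rng = np.random.default_rng(7)
        import statsmodels.api as sm
        n = 80
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)  # independent extra regressor
        y = 1 + 0.5 * x1 + 0.3 * x2 + rng.normal(0, 1, n)
        Xf = sm.add_constant(np.column_stack([x1, x2]))
        Xr = sm.add_constant(x1)
        full = sm.OLS(y, Xf).fit()
        red = sm.OLS(y, Xr).fit()
        F, df1, df2, p = f_test(full, red)
        assert df1 == 1
        assert F == pytest.approx(full.tvalues[2] ** 2, rel=1e-8)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(8)
        import statsmodels.api as sm
        y = rng.normal(size=30)
        a = sm.OLS(y, np.ones((30, 1))).fit()
        b = sm.OLS(y, sm.add_constant(rng.normal(size=30))).fit()
        with pytest.raises(ValueError):
            f_test(a, b)


class TestDailyProportion:
    dates = ["2012-01-01", "2012-01-15", "2012-01-29"]
    values = [0.1, 0.5, 0.9]

    def test_exact_date_returns_value(self):
        assert daily_fruiting_proportion(self.dates, self.values,
                                         "2012-01-15") == 0.5

    def test_tie_resolves_to_earlier(self):
        assert daily_fruiting_proportion(self.dates, self.values,
                                         "2012-01-08") == 0.1

    def test_nearest_neighbour(self):
        # one day after the first obs, thirteen before the second
        assert daily_fruiting_proportion(self.dates, self.values,
                                         "2012-01-02") == 0.1
        assert daily_fruiting_proportion(self.dates, self.values,
                                         "2012-01-25") == 0.9

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            daily_fruiting_proportion([], [], "2012-01-01")
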