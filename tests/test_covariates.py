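"""Site predictors: preference test, densities, human indices, offsets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nestmosaic.covariates import (
    NestingSiteRecord,
    human_forest_use,
    interpolate_community_size,
    preference_test,
    rainfall_window,
    suitable_tree_density,
    village_influence,
    z_transform,
)


class TestPreferenceTest:
    def test_proportional_use_gives_null_result(self):
        res = preference_test({"a": 5, "b": 5}, {"a": 50, "b": 50},
                              n_perm=2000, seed=0)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_permutation > 0.9
        assert res.preferred == []

    def test_permutation_matches_exact_binomial_tail(self):
        # 2 species, 50/50 abundance, 10/0 nests: exact p = 2 (1/2)^10
        n_perm = 40000
        res = preference_test({"a": 10, "b": 0}, {"a": 50, "b": 50},
                              n_perm=n_perm, seed=1)
        exact = 2 * 0.5**10
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p_permutation - exact) < 3 * se + 1.0 / n_perm

    def test_worked_binomial_example_flags_preference(self):
        # species with abundance share 0.1 gathering 5 of 10 nests
        res = preference_test({"a": 5, "b": 5}, {"a": 10, "b": 90},
                              n_perm=500, seed=2)
        expected_p = stats.binom.sf(4, 10, 0.1)
        assert expected_p == pytest.approx(0.0016, abs=2e-4)
        assert res.per_species.loc["a", "binomial_p"] == pytest.approx(
            expected_p, rel=1e-9)
        assert "a" in res.preferred

    def test_zero_nests_or_missing_abundance_rejected(self):
        with pytest.raises(ValueError):
            preference_test({"a": 0}, {"a": 10})
        with pytest.raises(ValueError):
            preference_test({"a": 3, "b": 1}, {"a": 10})


class TestSuitableTreeDensity:
    def site(self, nest, control):
        return NestingSiteRecord("s1", pd.Timestamp("2012-01-01"), (0, 0),
                                 "Nkala", nest, control)

    def test_no_preferred_species_zero(self):
        s = self.site(["x"] * 3, ["y"] * 5)
        assert suitable_tree_density(s, {"a"}) == 0.0

    def test_all_preferred_arithmetic(self):
        s = self.site(["a"] * 12, ["a"] * 8)
        assert suitable_tree_density(s, {"a"}, reference_area_ha=0.1) == 200.0

    def test_area_scaling(self):
        s = self.site(["a"] * 4, [])
        d1 = suitable_tree_density(s, {"a"}, reference_area_ha=0.1)
        d2 = suitable_tree_density(s, {"a"}, reference_area_ha=0.2)
        assert d1 == pytest.approx(2 * d2)
        with pytest.raises(ValueError):
            suitable_tree_density(s, {"a"}, reference_area_ha=0.0)


class TestVillageInfluence:
    def test_single_village(self):
        assert village_influence((0, 0), [(100, (2.0, 0.0))]) == 50.0

    def test_hand_sum(self):
        v = [(100, (2.0, 0.0)), (300, (10.0, 0.0))]
        assert village_influence((0, 0), v) == pytest.approx(80.0)

    def test_monotone_decay_with_distance(self):
        v = [(100, (2.0, 0.0)), (300, (10.0, 0.0))]
        near = village_influence((0, 0), v)
        far = village_influence((-3.0, 0), v)
        assert far < near

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            village_influence((2.0, 0.0), [(10, (2.0, 0.0))])


class TestHumanForestUse:
    villages = pd.DataFrame({"village": ["V"], "men": [10], "women": [4]})

    def quest(self, regions="R", freq=1.0):
        return pd.DataFrame({
            "village": ["V"], "activity": ["hunting"], "gender": ["M"],
            "person_id": ["p0"], "freq_per_day": [freq],
            "regions": [regions]})

    def test_single_hunter_formula_value(self):
        # (1/1)/1 interviewed x 10 men / 2 km^2 = 5
        idx = human_forest_use("R", self.quest(), self.villages,
                               region_area_km2=2.0)
        assert idx == pytest.approx(5.0)

    def test_region_not_visited_gives_zero(self):
        idx = human_forest_use("Elsewhere", self.quest(), self.villages, 2.0)
        assert idx == 0.0

    def test_area_scaling_and_region_split(self):
        # visiting two regions halves the per-region probability
        idx = human_forest_use("R", self.quest(regions="R;S"), self.villages,
                               2.0)
        assert idx == pytest.approx(2.5)
        assert human_forest_use("R", self.quest(), self.villages, 4.0) == \
            pytest.approx(2.5)

    def test_empty_questionnaire(self):
        empty = self.quest().iloc[0:0]
        assert human_forest_use("R", empty, self.villages, 2.0) == 0.0


class TestRainfallWindow:
    def test_constant_rain_totals(self):
        idx = pd.date_range("2012-01-01", periods=60, freq="D")
        rain = pd.Series(5.0, index=idx)
        assert rainfall_window(rain, "2012-02-15") == pytest.approx(150.0)

    def test_zero_series(self):
        idx = pd.date_range("2012-01-01", periods=60, freq="D")
        assert rainfall_window(pd.Series(0.0, index=idx), "2012-02-15") == 0.0

    def test_storm_on_day_31_excluded(self):
        idx = pd.date_range("2012-01-01", periods=60, freq="D")
        rain = pd.Series(0.0, index=idx)
        build = pd.Timestamp("2012-02-15")
        rain[build - pd.Timedelta(days=31)] = 40.0
        assert rainfall_window(rain, build) == 0.0
        rain[build - pd.Timedelta(days=30)] = 1.0
        assert rainfall_window(rain, build) == 1.0

    def test_gappy_window_warns(self):
        idx = pd.date_range("2012-02-10", periods=10, freq="D")
        rain = pd.Series(1.0, index=idx)
        with pytest.warns(UserWarning):
            total = rainfall_window(rain, "2012-02-15")
        assert total == 5.0


class TestCommunitySizeInterpolation:
    def test_on_survey_date(self):
        s = [("2012-01-01", 20.0), ("2012-04-10", 10.0)]
        assert interpolate_community_size(s, "2012-04-10") == 10.0

    def test_inverse_gap_weighting(self):
        s = [("2012-01-01", 20.0), ("2012-04-10", 10.0)]  # 100 days apart
        val = interpolate_community_size(s, "2012-01-26")  # t = 25
        assert val == pytest.approx(17.5)

    def test_midpoint_is_arithmetic_mean(self):
        s = [("2012-01-01", 20.0), ("2012-03-01", 10.0)]
        val = interpolate_community_size(s, "2012-01-31")
        assert val == pytest.approx(15.0)

    def test_outside_span_uses_nearest(self):
        s = [("2012-01-01", 20.0)]
        with pytest.warns(UserWarning):
            assert interpolate_community_size(s, "2013-01-01") == 20.0
        with pytest.raises(ValueError):
            interpolate_community_size([], "2012-01-01")


class TestZTransform:
    def test_reference_case(self):
        assert np.allclose(z_transform([1, 2, 3]), [-1, 0, 1])

    def test_idempotence(self):
        x = z_transform(np.random.default_rng(0).normal(3, 2, 50))
        assert np.allclose(z_transform(x), x, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        assert np.allclose(z_transform(2.5 * x + 7.0), z_transform(x),
                           atol=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            z_transform([4.0, 4.0, 4.0])
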