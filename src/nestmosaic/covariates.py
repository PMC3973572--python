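"""Per-nesting-site predictors for the cohesiveness models.

A nesting site is a cluster of same-night nests (pairwise distance <= 30 m);
its nest count proxies night party size.  This module derives every site
predictor used downstream: preferred-nesting-tree density (permutation
chi-square plus per-species binomial tests against forest abundance), fruit
availability at the site and over the 14 days before building at forest
scale, village influence (sum of population/distance), the questionnaire
based human-forest-use index, the 30-day rainfall total, and the
time-weighted interpolation of community size used as the model offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phenology import daily_fruiting_proportion, fruit_index

__all__ = [
    "NestingSiteRecord",
    "PreferenceResult",
    "preference_test",
    "suitable_tree_density",
    "village_influence",
    "human_forest_use",
    "rainfall_window",
    "site_fruit_availability",
    "forest_fruit_availability_14d",
    "interpolate_community_size",
    "z_transform",
]

#: default reference area of a nesting site: a 30 m radius disc, in ha
SITE_REFERENCE_HA = float(np.pi * 0.03**2 * 100)  # 0.2827 ha


@dataclass
class NestingSiteRecord:
    """One nesting site: nests counted within the 30 m same-site rule."""

    site_id: str
    date_built: pd.Timestamp
    location_km: tuple
    forest: str
    nest_trees: list = field(default_factory=list)
    control_trees: list = field(default_factory=list)
    nest_count: int = 0

    def __post_init__(self):
        if self.nest_count == 0:
            self.nest_count = len(self.nest_trees)
        if self.nest_count < 1:
            raise ValueError(f"site {self.site_id}: needs at least one nest")


@dataclass
class PreferenceResult:
    """Nesting-tree preference test output."""

    chi2: float
    p_permutation: float
    per_species: pd.DataFrame     # observed, expected, binomial p
    preferred: list
    n_perm: int

    def summary(self):
        return (f"Nesting-tree preference: chi2 = {self.chi2:.2f}, "
                f"permutation p = {self.p_permutation:.4g} "
                f"({self.n_perm} resamples)\n"
                f"preferred species (alpha = 0.05): "
                + (", ".join(self.preferred) if self.preferred else "none"))


def preference_test(nest_counts_by_species, forest_abundance_by_species,
                    n_perm=10000, seed=None, alpha=0.05):
    """Do apes prefer some tree species for nest building?

    Observed nest counts per species are compared with the expectation
    under proportional use of forest abundance.  The chi-square statistic's
    p-value comes from multinomial permutation under the abundance null
    (with the +1/(n_perm+1) correction), and one-sided exact binomial tests
    per species flag the preferred set (p < alpha).
    """
    obs = pd.Series(nest_counts_by_species, dtype=float)
    ab = pd.Series(forest_abundance_by_species, dtype=float)
    ab = ab.reindex(obs.index)
    if ab.isna().any() or (ab <= 0).any():
        raise ValueError("every tested species needs positive forest "
                         "abundance (merge to genus or drop first)")
    n_total = obs.sum()
    if n_total <= 0:
        raise ValueError("no nests to test")
    p_null = (ab / ab.sum()).to_numpy()
    expected = n_total * p_null
    chi2 = float(((obs.to_numpy() - expected) ** 2 / expected).sum())

    rng = np.random.default_rng(seed)
    draws = rng.multinomial(int(n_total), p_null, size=int(n_perm))
    chi2_null = (((draws - expected) ** 2) / expected).sum(axis=1)
    p_perm = (1.0 + np.sum(chi2_null >= chi2 - 1e-12)) / (n_perm + 1.0)

    binom_p = np.array([
        stats.binomtest(int(k), int(n_total), p, alternative="greater").pvalue
        for k, p in zip(obs.to_numpy(), p_null)
    ])
    per_species = pd.DataFrame({
        "observed": obs.to_numpy(),
        "expected": expected,
        "abundance_share": p_null,
        "binomial_p": binom_p,
    }, index=obs.index)
    preferred = list(per_species.index[binom_p < alpha])
    return PreferenceResult(chi2=chi2, p_permutation=float(p_perm),
                            per_species=per_species, preferred=preferred,
                            n_perm=int(n_perm))


def suitable_tree_density(site, preferred, reference_area_ha=SITE_REFERENCE_HA):
    """Density (stems/ha) of preferred species among the site's trees.

    Counts preferred-species stems among nest plus control trees over a
    fixed reference area (a 30 m radius disc by default — the same-site
    rule radius; the field protocol does not define a site area, so this
    is a configuration constant).
    """
    if reference_area_ha <= 0:
        raise ValueError("reference area must be positive")
    pref = set(preferred)
    trees = list(site.nest_trees) + list(site.control_trees)
    return sum(1 for sp in trees if sp in pref) / reference_area_ha


def village_influence(site_location_km, villages):
    """Sum over villages of population / distance (km).

    ``villages`` is an iterable of ``(population, (x_km, y_km))`` or a
    DataFrame with ``population, x_km, y_km``.
    """
    if isinstance(villages, pd.DataFrame):
        villages = [(r["population"], (r["x_km"], r["y_km"]))
                    for _, r in villages.iterrows()]
    sx, sy = site_location_km
    total = 0.0
    for pop, (vx, vy) in villages:
        d = float(np.hypot(sx - vx, sy - vy))
        if d == 0:
            raise ValueError("site coincides with a village (zero distance)")
        total += pop / d
    return total


def human_forest_use(forest_region, questionnaire, villages, region_area_km2):
    """Daily adults potentially entering a forest region, per km^2.

    For each (village, activity): every interviewed person contributes
    freq_per_day / n_regions_visited if the region is among the regions
    they visit; the village-activity term is that sum divided by the number
    interviewed for the activity, scaled by the village's gender-matched
    adult count.  Terms are summed over villages and activities and divided
    by the region area.  The result is log-transformed downstream.

    Parameters
    ----------
    questionnaire : DataFrame
        Columns ``village, activity, gender, freq_per_day, regions``
        (regions = iterable or ";"-separated string of region labels).
    villages : DataFrame
        Columns ``village, men, women``.
    """
    if region_area_km2 <= 0:
        raise ValueError("region area must be positive")
    q = questionnaire.copy()
    if len(q) == 0:
        return 0.0
    vil = villages.set_index("village")
    total = 0.0
    for (village, activity), grp in q.groupby(["village", "activity"]):
        n_interviewed = len(grp)
        if n_interviewed == 0:
            continue
        genders = grp["gender"].unique()
        if len(genders) > 1:
            raise ValueError(f"activity {activity!r} mixes genders; "
                             "activities are gender-specific")
        contrib = 0.0
        for _, person in grp.iterrows():
            regions = person["regions"]
            if isinstance(regions, str):
                regions = [r for r in regions.split(";") if r]
            regions = list(regions)
            if forest_region in regions:
                contrib += person["freq_per_day"] / len(regions)
        prop_quest_adult = contrib / n_interviewed
        adults = vil.loc[village, "men" if genders[0] == "M" else "women"]
        total += prop_quest_adult * float(adults)
    return total / region_area_km2


def rainfall_window(rain_series, date_built, window_days=30,
                    missing_warn_fraction=0.2):
    """Total rainfall (mm) over the ``window_days`` days strictly before
    ``date_built``.

    ``rain_series`` is a pandas Series indexed by date.  Days missing from
    the window are tolerated; if more than ``missing_warn_fraction`` of the
    window is missing a warning is raised and the partial sum returned.
    """
    t1 = pd.Timestamp(date_built)
    t0 = t1 - pd.Timedelta(days=window_days)
    idx = pd.to_datetime(rain_series.index)
    mask = (idx >= t0) & (idx < t1)
    covered = int(mask.sum())
    if covered < window_days * (1 - missing_warn_fraction):
        warnings.warn(f"rainfall window before {t1.date()} missing "
                      f"{window_days - covered}/{window_days} days")
    return float(np.asarray(rain_series)[mask].sum())


def site_fruit_availability(site_trees, basal_areas, species=None):
    """Fruit index restricted to the site's own tree list.

    ``site_trees``: DataFrame with ``species, n_trees, n_fruiting`` for the
    trees at the nesting site.
    """
    t = site_trees.copy()
    t["unit"] = "site"
    out = fruit_index(t, basal_areas, species=species, by=("unit",))
    return float(out["value"].iloc[0]) if len(out) else 0.0


def forest_fruit_availability_14d(daily_obs, basal_areas, date_built,
                                  species=None, window_days=14):
    """Mean fruiting proportion over the 14 days before building x basal
    area, summed over the fleshy-fruit species set.

    ``daily_obs``: DataFrame with ``species, date, proportion`` (biweekly
    observations; each day in the window takes the nearest observation via
    :func:`nestmosaic.phenology.daily_fruiting_proportion`).
    ``basal_areas``: per-species basal area for the relevant unit (global
    for the one-community model, forest-specific for the two-community one).
    """
    t1 = pd.Timestamp(date_built)
    days = [t1 - pd.Timedelta(days=k) for k in range(1, window_days + 1)]
    ba = basal_areas.set_index("species")["basal_m2_ha"]
    total = 0.0
    for sp, grp in daily_obs.groupby("species"):
        if species is not None and sp not in set(species):
            continue
        if sp not in ba.index:
            continue
        props = [daily_fruiting_proportion(grp["date"], grp["proportion"], d)
                 for d in days]
        total += float(np.mean(props)) * float(ba.loc[sp])
    return total


def interpolate_community_size(surveys, date_built):
    """Community size at the build date, weighted by time to the bracketing
    surveys.

    ``surveys``: iterable of ``(date, size)``.  With one survey before and
    one after, weights are the inverse time gaps (equivalently, linear
    interpolation in time).  Outside the surveyed span the nearest survey
    is used (flagged with a warning).
    """
    pts = sorted((pd.Timestamp(d), float(s)) for d, s in surveys)
    if not pts:
        raise ValueError("no community-size surveys supplied")
    t = pd.Timestamp(date_built)
    before = [(d, s) for d, s in pts if d <= t]
    after = [(d, s) for d, s in pts if d >= t]
    if before and after and before[-1][0] == after[0][0]:
        return after[0][1]
    if not before:
        warnings.warn("build date precedes all surveys; using the first")
        return pts[0][1]
    if not after:
        warnings.warn("build date follows all surveys; using the last")
        return pts[-1][1]
    (d0, s0), (d1, s1) = before[-1], after[0]
    g0 = (t - d0).total_seconds()
    g1 = (d1 - t).total_seconds()
    w0, w1 = 1.0 / g0, 1.0 / g1
    return (w0 * s0 + w1 * s1) / (w0 + w1)


def z_transform(x):
    """Standardize to mean 0, sample (n-1) standard deviation 1."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-transform a constant vector")
    out = (x - x.mean()) / sd
    assert abs(out.mean()) < 1e-10 and abs(out.std(ddof=1) - 1) < 1e-10
    return out
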