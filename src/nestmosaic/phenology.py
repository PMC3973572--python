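"""Fleshy-fruit availability indices and their seasonality.

The fruit availability index for a unit (forest, plot, nesting site or the
whole study area) on a date is

    index = sum_species  (proportion of that species' trees fruiting)
                         x (basal area of the species in the unit, m^2/ha),

summed over the configured fleshy-fruit species set.  Seasonality is
modelled with a Gaussian linear model on a power-transformed index: the
date becomes a circular variable (angle = 2 pi doy / 365.25) entering
through its sine and cosine, with forest as a categorical predictor, an
optional forest x season interaction, and a temporal Gaussian-kernel
autocovariate (distance in days) sharing the machinery of
:mod:`nestmosaic.kernels`.  Nested models are compared with F-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from . import kernels

__all__ = [
    "fruit_index",
    "basal_area_table",
    "estimate_power_transform",
    "PowerTransform",
    "SeasonalFruitModel",
    "SeasonalModelResult",
    "f_test",
    "daily_fruiting_proportion",
]

PERIOD_DAYS = 365.25


def date_angle(dates):
    """Circular date: angle = 2 pi day-of-year / 365.25."""
    doy = pd.DatetimeIndex(pd.to_datetime(dates)).dayofyear.to_numpy(dtype=float)
    return 2.0 * np.pi * doy / PERIOD_DAYS


def basal_area_table(trees, area_ha, by=None):
    """Per-species basal area (m^2/ha) from stem DBH records.

    ``trees`` needs columns ``species`` and ``dbh_cm``; basal area per stem
    is pi (DBH/2)^2 and the species total is divided by the sampled
    hectares.  ``by`` adds grouping columns (e.g. ``["forest"]``) with
    ``area_ha`` then a mapping group -> hectares.
    """
    t = trees.copy()
    t["ba_m2"] = np.pi * (t["dbh_cm"].to_numpy(dtype=float) / 200.0) ** 2
    if by is None:
        out = t.groupby("species", as_index=False)["ba_m2"].sum()
        out["basal_m2_ha"] = out["ba_m2"] / float(area_ha)
    else:
        out = t.groupby(list(by) + ["species"], as_index=False)["ba_m2"].sum()
        key = out[by[0]] if len(by) == 1 else out[by].apply(tuple, axis=1)
        out["basal_m2_ha"] = out["ba_m2"] / key.map(area_ha).astype(float)
    return out.drop(columns="ba_m2")


def fruit_index(fruiting_obs, basal_areas, species=None, by=("forest", "date")):
    """Fruit availability index per unit.

    Parameters
    ----------
    fruiting_obs : DataFrame
        Columns ``species, n_trees, n_fruiting`` plus the ``by`` columns.
    basal_areas : DataFrame
        Columns ``species, basal_m2_ha`` and optionally ``forest`` for
        forest-specific basal areas.
    species : iterable, optional
        The fleshy-fruit species set; defaults to every species present.
    """
    obs = fruiting_obs.copy()
    if species is not None:
        obs = obs[obs["species"].isin(set(species))]
    if ((obs["n_fruiting"] < 0) | (obs["n_fruiting"] > obs["n_trees"])).any():
        raise ValueError("fruiting counts must lie in [0, n_trees]")
    obs["proportion"] = np.where(obs["n_trees"] > 0,
                                 obs["n_fruiting"] / obs["n_trees"], 0.0)
    keys = ["species"] + (["forest"] if "forest" in basal_areas.columns
                          and "forest" in obs.columns else [])
    merged = obs.merge(basal_areas[keys + ["basal_m2_ha"]], on=keys, how="left")
    missing = merged.loc[merged["basal_m2_ha"].isna(), "species"].unique()
    if len(missing):
        warnings.warn("species without basal area excluded from index: "
                      + ", ".join(sorted(map(str, missing))))
        merged = merged.dropna(subset=["basal_m2_ha"])
    merged["term"] = merged["proportion"] * merged["basal_m2_ha"]
    out = merged.groupby(list(by), as_index=False)["term"].sum()
    return out.rename(columns={"term": "value"})


# ----------------------------------------------------------------------
# power transform
# ----------------------------------------------------------------------

@dataclass
class PowerTransform:
    """Box-Cox power transform estimated by profile likelihood."""

    lambda_: float
    loglik: float

    def transform(self, y):
        y = np.asarray(y, dtype=float)
        if abs(self.lambda_) < 1e-12:
            return np.log(y)
        return (y**self.lambda_ - 1.0) / self.lambda_


def _boxcox_profile_loglik(lam, y, X):
    if abs(lam) < 1e-12:
        yt = np.log(y)
    else:
        yt = (y**lam - 1.0) / lam
    beta, *_ = np.linalg.lstsq(X, yt, rcond=None)
    resid = yt - X @ beta
    n = len(y)
    rss = float(resid @ resid)
    if rss <= 0:
        return np.inf
    return -n / 2.0 * np.log(rss / n) + (lam - 1.0) * np.sum(np.log(y))


def estimate_power_transform(response, design, bounds=(-3.0, 3.0)):
    """Box-Cox lambda making regression residuals closest to normal.

    Maximizes the profile normal likelihood of the linear model of the
    transformed response on ``design`` (which must include its intercept).
    """
    y = np.asarray(response, dtype=float)
    if np.any(y <= 0):
        raise ValueError("response must be strictly positive; shift it first")
    X = np.asarray(design, dtype=float)
    res = optimize.minimize_scalar(
        lambda lam: -_boxcox_profile_loglik(lam, y, X),
        bounds=bounds, method="bounded", options={"xatol": 1e-5})
    return PowerTransform(lambda_=float(res.x), loglik=float(-res.fun))


# ----------------------------------------------------------------------
# seasonal model
# ----------------------------------------------------------------------

class SeasonalModelResult:
    """Wraps the OLS fit of the seasonal fruit model."""

    def __init__(self, ols_results, lambda_, ac_sd_days=None):
        self.ols = ols_results
        self.lambda_ = lambda_
        self.ac_sd_days = ac_sd_days

    @property
    def params(self):
        return self.ols.params

    @property
    def llf(self):
        return float(self.ols.llf)

    @property
    def amplitude(self):
        return float(np.hypot(self.params.get("sin_date", 0.0),
                              self.params.get("cos_date", 0.0)))

    @property
    def phase(self):
        return float(np.arctan2(self.params.get("sin_date", 0.0),
                                self.params.get("cos_date", 0.0)))

    def conf_int(self, alpha=0.05):
        return self.ols.conf_int(alpha)

    def summary(self):
        head = (f"Seasonal fruit availability model "
                f"(lambda = {self.lambda_:.3f}"
                + (f", AC sd = {self.ac_sd_days:.1f} d" if self.ac_sd_days
                   else "") + ")\n")
        tab = pd.DataFrame({
            "estimate": self.ols.params,
            "se": self.ols.bse,
            "t": self.ols.tvalues,
            "p": self.ols.pvalues,
        })
        return head + tab.round(4).to_string() + (
            f"\namplitude = {self.amplitude:.4f}, phase = {self.phase:.4f} rad")

    def plot(self, ax=None):
        """Observed (transformed) index and fitted values against date."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ols.model.data.endog, "o", ms=3, label="observed")
        ax.plot(self.ols.fittedvalues.to_numpy()
                if hasattr(self.ols.fittedvalues, "to_numpy")
                else self.ols.fittedvalues, "-", label="fitted")
        ax.set_xlabel("observation")
        ax.set_ylabel("transformed fruit index")
        ax.legend()
        return ax


class SeasonalFruitModel:
    """Gaussian seasonality model for biweekly forest fruit-index series.

    Parameters
    ----------
    series : DataFrame
        Columns ``date, forest, value`` (value > 0); the biweekly
        forest-level index from :func:`fruit_index`.
    lambda_ : float, optional
        Power-transform parameter; estimated by profile likelihood on the
        no-interaction design when omitted.
    """

    def __init__(self, series, lambda_=None):
        s = series.copy()
        s["date"] = pd.to_datetime(s["date"])
        if (s["value"] <= 0).any():
            raise ValueError("fruit index must be positive for the power "
                             "transform; shift or filter first")
        self.series = s.sort_values("date").reset_index(drop=True)
        self.forest_levels = sorted(self.series["forest"].unique())
        if len(self.forest_levels) < 2:
            warnings.warn("single forest: forest effect not estimable")
        self._angle = date_angle(self.series["date"])
        self._days = (self.series["date"]
                      - self.series["date"].min()).dt.days.to_numpy(float)
        self.lambda_ = lambda_

    def _design(self, include_interaction=False, ac=None):
        X = pd.DataFrame({"const": np.ones(len(self.series))})
        for lev in self.forest_levels[1:]:
            X[f"forest[{lev}]"] = (self.series["forest"] == lev).astype(float)
        X["sin_date"] = np.sin(self._angle)
        X["cos_date"] = np.cos(self._angle)
        if include_interaction:
            for lev in self.forest_levels[1:]:
                ind = (self.series["forest"] == lev).astype(float)
                X[f"sin_date:forest[{lev}]"] = X["sin_date"] * ind
                X[f"cos_date:forest[{lev}]"] = X["cos_date"] * ind
        if ac is not None:
            X["ac_term"] = ac
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ValueError("rank-deficient design; aliased columns among "
                             + ", ".join(X.columns))
        return X

    def _transformed(self, include_interaction=False):
        if self.lambda_ is None:
            pt = estimate_power_transform(
                self.series["value"], self._design(include_interaction))
            self.lambda_ = pt.lambda_
        return PowerTransform(self.lambda_, np.nan).transform(
            self.series["value"])

    def fit(self, include_interaction=False, ac_sd_days=None, sd_grid=None):
        """Fit the seasonal model.

        ``ac_sd_days`` may be a number (use that temporal bandwidth),
        ``"optimize"`` (profile the refitted likelihood over ``sd_grid``,
        default 1-120 days log-spaced), or None (no autocovariate).
        """
        yt = self._transformed(include_interaction)
        base = sm.OLS(yt, self._design(include_interaction)).fit()
        if ac_sd_days is None:
            return SeasonalModelResult(base, self.lambda_)
        resid = np.asarray(base.resid, dtype=float)

        def fit_at(sd):
            ac = kernels.autocovariate(self._days, resid, sd)
            return sm.OLS(yt, self._design(include_interaction, ac=ac)).fit()

        if ac_sd_days == "optimize":
            grid = (np.geomspace(1.0, 120.0, 15) if sd_grid is None
                    else np.asarray(sd_grid, dtype=float))
            lls = [fit_at(sd).llf for sd in grid]
            sd = float(grid[int(np.argmax(lls))])
        else:
            sd = float(ac_sd_days)
        return SeasonalModelResult(fit_at(sd), self.lambda_, ac_sd_days=sd)


def f_test(full, reduced):
    """Extra-sum-of-squares F-test of nested Gaussian fits.

    Accepts :class:`SeasonalModelResult` or statsmodels OLS results;
    returns ``(F, df1, df2, p)``.
    """
    f = full.ols if isinstance(full, SeasonalModelResult) else full
    r = reduced.ols if isinstance(reduced, SeasonalModelResult) else reduced
    if f.df_model < r.df_model:
        raise ValueError("full model must nest the reduced model")
    if f.df_model == r.df_model:
        return 0.0, 0, int(f.df_resid), 1.0
    fval, pval, df_diff = f.compare_f_test(r)
    return float(fval), int(df_diff), int(f.df_resid), float(pval)


def daily_fruiting_proportion(obs_dates, obs_values, date):
    """Proportion at ``date`` = value of the nearest observation.

    Ties (query exactly midway) resolve to the earlier observation.
    """
    d = pd.to_datetime(pd.Series(obs_dates)).to_numpy()
    v = np.asarray(obs_values, dtype=float)
    if len(d) == 0:
        raise ValueError("need at least one observation")
    order = np.argsort(d, kind="stable")
    d, v = d[order], v[order]
    q = pd.Timestamp(date).to_datetime64()
    gaps = np.abs((d - q) / np.timedelta64(1, "s"))
    best = np.flatnonzero(gaps == gaps.min())[0]  # earlier wins ties
    return float(v[best])
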