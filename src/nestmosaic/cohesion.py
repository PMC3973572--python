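"""Nest-group size under one- vs two-community hypotheses.

Nest count per nesting site (a proxy for night party size) is modelled
with a negative-binomial GLM (log link).  Community size enters as an
offset — log of the interpolated number of nest-building individuals: the
one-community model (Model 1) offsets by the summed builders of both
forests, the two-community model (Model 2) by the builders of the site's
own forest.  The six predictors (density of suitable nesting trees, fruit
availability in the forest over the previous 14 days, fruit availability
at the site, village influence, log human forest use, 30-day rainfall) are
z-transformed.  Residual structure is absorbed by a joint spatio-temporal
autocovariate whose two kernel standard deviations are profiled
simultaneously; the term is kept only while significant.  Hypotheses are
compared by AICc and the environmental block by a likelihood-ratio
chi-square against a null with only the human controls and the offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from . import kernels
from .covariates import z_transform

__all__ = [
    "PREDICTORS",
    "CohesionModel",
    "CohesionResult",
    "ComparisonResult",
    "fit_cohesion",
    "spatiotemporal_autocovariate",
    "optimize_two_bandwidths",
    "aicc",
    "compare_hypotheses",
    "environmental_block_test",
    "leverage_screen",
]

PREDICTORS = (
    "density_suitable_trees",
    "fruit_forest_14d",
    "fruit_site",
    "village_influence",
    "human_forest_use",
    "rainfall_30d",
)
HUMAN_CONTROLS = ("village_influence", "human_forest_use")


class CohesionResult:
    """Negative-binomial nest-group-size fit (wraps the statsmodels NB2)."""

    def __init__(self, nb_results, predictors, offset_name):
        self.nb = nb_results
        self.predictors = tuple(predictors)
        self.offset_name = offset_name

    @property
    def params(self):
        return self.nb.params

    @property
    def llf(self):
        return float(self.nb.llf)

    @property
    def k_params(self):
        return len(self.nb.params)  # includes the NB dispersion alpha

    @property
    def nobs(self):
        return int(self.nb.nobs)

    @property
    def aic(self):
        return 2 * self.k_params - 2 * self.llf

    @property
    def aicc(self):
        return aicc(self.llf, self.k_params, self.nobs)

    @property
    def alpha(self):
        return float(self.nb.params.iloc[-1])

    @property
    def table(self):
        return pd.DataFrame({
            "estimate": self.nb.params,
            "se": self.nb.bse,
            "z": self.nb.tvalues,
            "p": self.nb.pvalues,
        })

    def fitted_mean(self):
        return np.asarray(self.nb.predict())

    def summary(self):
        return (f"Nest-group size NB model (offset = log {self.offset_name})\n"
                f"n = {self.nobs}  loglik = {self.llf:.3f}  "
                f"AIC = {self.aic:.2f}  AICc = {self.aicc:.2f}\n"
                + self.table.round(4).to_string())

    def plot(self, against, ax=None, label=None):
        """Nest counts against one (z-scored) predictor with fitted means."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.asarray(against, dtype=float)
        y = self.nb.model.endog
        ax.scatter(x, y, s=12, alpha=0.6, label="sites")
        order = np.argsort(x)
        ax.plot(x[order], self.fitted_mean()[order], "k-", lw=1,
                label="fitted mean")
        ax.set_xlabel(label or "predictor (z)")
        ax.set_ylabel("nests at site")
        ax.legend()
        return ax


class CohesionModel:
    """Nest-group-size model under a community hypothesis.

    Parameters
    ----------
    data : DataFrame
        One row per nesting site with ``nest_count``, the predictor
        columns, ``builders_forest`` and ``builders_total``, plus
        ``x_km, y_km, date_built`` when an autocovariate is wanted.
    hypothesis : {"one_community", "two_communities"}
        Chooses the offset: pooled builders vs the site's own forest.
    """

    def __init__(self, data, hypothesis="two_communities",
                 predictors=PREDICTORS, log_human_use=True):
        if hypothesis not in ("one_community", "two_communities"):
            raise ValueError(f"unknown hypothesis {hypothesis!r}")
        self.data = data
        self.hypothesis = hypothesis
        self.predictors = tuple(predictors)
        self.log_human_use = log_human_use
        self.offset_col = ("builders_total" if hypothesis == "one_community"
                           else "builders_forest")

    def fit(self, ac="optimize", drop_alpha=0.05, grid_s=None, grid_t=None):
        """Fit the NB model, optionally profiling the space-time term.

        ``ac`` is "optimize" (joint bandwidth search with the drop rule),
        None (no term), or a precomputed vector.
        """
        if ac is None:
            return fit_cohesion(self.data, self.offset_col, self.predictors,
                                log_human_use=self.log_human_use)
        if isinstance(ac, str) and ac == "optimize":
            _, _, fit, _, _ = optimize_two_bandwidths(
                self.data, self.offset_col, self.predictors,
                grid_s=grid_s, grid_t=grid_t, drop_alpha=drop_alpha,
                log_human_use=self.log_human_use)
            return fit
        return fit_cohesion(self.data, self.offset_col, self.predictors,
                            ac=ac, log_human_use=self.log_human_use)


def _design(data, predictors, ac=None, log_human_use=True, standardize=True):
    X = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    for p in predictors:
        x = data[p].to_numpy(dtype=float)
        if p == "human_forest_use" and log_human_use:
            if np.any(x <= 0):
                warnings.warn("non-positive human forest use: using log1p")
                x = np.log1p(x)
            else:
                x = np.log(x)
        if standardize:
            x = z_transform(x)
        X[p] = x
    if ac is not None:
        X["ac_term"] = np.asarray(ac, dtype=float)
    return X


def fit_cohesion(data, offset_col="builders", predictors=PREDICTORS, ac=None,
                 log_human_use=True, standardize=True):
    """Fit the NB nest-group-size model.

    ``data`` needs ``nest_count``, the predictor columns and ``offset_col``
    (interpolated nest-building community size, > 0).
    """
    y = data["nest_count"].to_numpy(dtype=float)
    off = np.asarray(data[offset_col], dtype=float)
    if np.any(off <= 0):
        raise ValueError("community-size offset must be positive")
    n, p = len(y), len(predictors)
    if n < p + 2:
        raise ValueError("too few sites for the number of predictors")
    X = _design(data, predictors, ac=ac, log_human_use=log_human_use,
                standardize=standardize)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X, offset=np.log(off))
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = model.fit(method="nm", maxiter=5000, disp=0)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(start_params=res.params, method="nm",
                            maxiter=5000, disp=0)
    return CohesionResult(res, predictors, offset_name=offset_col)


def spatiotemporal_autocovariate(locations_km, dates, residuals,
                                 sd_spatial_km, sd_temporal_days):
    """Joint space-time autocovariate over nesting sites."""
    days = (pd.to_datetime(pd.Series(dates))
            - pd.to_datetime(pd.Series(dates)).min()).dt.days.to_numpy(float)
    return kernels.spatiotemporal_autocovariate(
        locations_km, days, residuals, sd_spatial_km, sd_temporal_days)


def optimize_two_bandwidths(data, offset_col="builders", predictors=PREDICTORS,
                            grid_s=None, grid_t=None, drop_alpha=0.05,
                            log_human_use=True):
    """Joint grid search for the two autocovariate bandwidths.

    Residuals come from the full model without the term; every (sd_s, sd_t)
    pair is refitted with the derived autocovariate and the likelihood
    recorded.  The winning term is retained only if significant at
    ``drop_alpha`` — otherwise the model without it is returned (flagged).
    Returns ``(sd_s, sd_t, fit, retained, profile)``.
    """
    if grid_s is None:
        grid_s = np.geomspace(0.25, 10.0, 6)
    if grid_t is None:
        grid_t = np.geomspace(5.0, 120.0, 6)
    base = fit_cohesion(data, offset_col, predictors,
                        log_human_use=log_human_use)
    resid = data["nest_count"].to_numpy(float) - base.fitted_mean()
    loc = data[["x_km", "y_km"]].to_numpy(float)
    dates = data["date_built"]

    rows = []
    best = (None, None, -np.inf, None)
    for ss in np.asarray(grid_s, float):
        for st in np.asarray(grid_t, float):
            try:
                ac = spatiotemporal_autocovariate(loc, dates, resid, ss, st)
                fit = fit_cohesion(data, offset_col, predictors, ac=ac,
                                   log_human_use=log_human_use)
                rows.append((ss, st, fit.llf))
                if fit.llf > best[2]:
                    best = (ss, st, fit.llf, fit)
            except Exception:
                rows.append((ss, st, np.nan))
    profile = pd.DataFrame(rows, columns=["sd_spatial_km", "sd_temporal_days",
                                          "loglik"])
    if best[3] is None:
        raise RuntimeError("no bandwidth pair could be fitted")
    ss, st, _, fit = best
    p_ac = float(fit.table.loc["ac_term", "p"])
    retained = p_ac < drop_alpha
    if retained:
        fit.ac_values = spatiotemporal_autocovariate(loc, dates, resid, ss, st)
    else:
        fit = base
        fit.ac_values = None
    return ss, st, fit, retained, profile


def aicc(loglik, k, n):
    """AIC with small-sample correction: AIC + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError("AICc needs n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ComparisonResult:
    """AICc comparison of the one- vs two-community hypotheses."""

    aicc_model1: float
    aicc_model2: float
    winner: str
    delta: float
    block_test: tuple = None

    def summary(self):
        out = (f"Model 1 (one community)  AICc = {self.aicc_model1:.2f}\n"
               f"Model 2 (two communities) AICc = {self.aicc_model2:.2f}\n"
               f"winner: {self.winner} (delta = {self.delta:.2f})")
        if self.block_test is not None:
            chi2, df, p = self.block_test
            out += (f"\nenvironmental block: chi2 = {chi2:.2f}, df = {df}, "
                    f"p = {p:.4g}")
        return out


def compare_hypotheses(fit1, fit2):
    """Pick the community hypothesis by minimum AICc."""
    if fit1.nobs != fit2.nobs:
        raise ValueError("hypotheses must be fitted to the same sites")
    a1, a2 = fit1.aicc, fit2.aicc
    delta = abs(a1 - a2)
    if a1 == a2:
        winner = "tie"
    else:
        winner = "one_community" if a1 < a2 else "two_communities"
    return ComparisonResult(aicc_model1=a1, aicc_model2=a2, winner=winner,
                            delta=delta)


def environmental_block_test(full, null):
    """LR chi-square of the four environmental predictors jointly.

    ``null`` is the fit with only the intercept, the two human controls,
    any autocovariate, and the offset.
    """
    df = full.k_params - null.k_params
    if df <= 0:
        raise ValueError("null model must be nested in the full model")
    chi2 = max(2.0 * (full.llf - null.llf), 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def leverage_screen(fit, threshold_factor=3.0):
    """Flag high-leverage sites via the weighted hat matrix.

    Working weights for the NB2 log link are mu / (1 + alpha mu); leverage
    above ``threshold_factor * k / n`` is flagged.  Returns the retained
    index array and a per-site report.
    """
    X = np.asarray(fit.nb.model.exog, dtype=float)
    mu = fit.fitted_mean()
    alpha = max(fit.alpha, 1e-8)
    w = mu / (1.0 + alpha * mu)
    Xw = X * np.sqrt(w)[:, None]
    hat = Xw @ np.linalg.pinv(Xw.T @ Xw) @ Xw.T
    h = np.diag(hat)
    n, k = X.shape
    cutoff = threshold_factor * k / n
    flagged = h > cutoff
    report = pd.DataFrame({"leverage": h, "flagged": flagged})
    return np.flatnonzero(~flagged), report
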