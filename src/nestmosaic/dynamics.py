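"""Between-year dynamics of per-transect nest counts.

Nest counts on transects are frequently zero but occasionally large, so
between-year variation is modelled with a zero-inflated negative binomial
(ZINB) regression: a logit model for structural absence mixed with an NB2
count model (log link).  Effort enters as offsets — log(length) in the
count part and log(1/length) in the zero part, both with fixed coefficient
one.  Residual spatial autocorrelation is absorbed by an autocovariate (the
Gaussian-kernel weighted average of the other transects' response-scale
residuals, see :mod:`nestmosaic.kernels`) added to the count part only; its
kernel standard deviation is chosen to maximize the likelihood of the full
model with the autocovariate included.

The ZINB likelihood is implemented here directly because the two-offset
structure (in particular the fixed zero-part offset) is not expressible in
off-the-shelf zero-inflated fitters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

from . import kernels

__all__ = [
    "ZeroInflatedNestCounts",
    "CountModelResult",
    "fit_zinb",
    "build_autocovariate",
    "optimize_bandwidth",
    "lr_test",
    "relevel_year",
    "jackknife_influence",
]


def _nb2_logpmf(y, mu, alpha):
    r = 1.0 / alpha
    return (special.gammaln(y + r) - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * (np.log(r) - np.log(r + mu))
            + y * (np.log(mu) - np.log(r + mu)))


class CountModelResult:
    """Results of a (zero-inflated) negative binomial count model."""

    def __init__(self, params, names_count, names_zero, llf, nobs, model=None,
                 cov=None, converged=True):
        self.params = np.asarray(params, dtype=float)
        self.names_count = list(names_count)
        self.names_zero = list(names_zero)
        self.llf = float(llf)
        self.nobs = int(nobs)
        self.model = model
        self.cov = cov
        self.converged = bool(converged)
        kz = len(self.names_zero)
        kc = len(self.names_count)
        self._slice_zero = slice(0, kz)
        self._slice_count = slice(kz, kz + kc)
        self.alpha = float(np.exp(self.params[-1]))

    # ------------------------------------------------------------------
    @property
    def k_params(self):
        return len(self.params)

    @property
    def aic(self):
        return 2 * self.k_params - 2 * self.llf

    @property
    def theta(self):
        """NB size parameter (1/alpha); large values mean Poisson-like."""
        return 1.0 / self.alpha

    @property
    def count_params(self):
        return pd.Series(self.params[self._slice_count], index=self.names_count)

    @property
    def zero_params(self):
        return pd.Series(self.params[self._slice_zero], index=self.names_zero)

    def _part_frame(self, sl, names):
        est = self.params[sl]
        if self.cov is not None:
            se = np.sqrt(np.diag(self.cov))[sl]
        else:
            se = np.full(len(est), np.nan)
        z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": est, "se": se, "z": z, "p": p}, index=names)

    @property
    def count_table(self):
        return self._part_frame(self._slice_count, self.names_count)

    @property
    def zero_table(self):
        return self._part_frame(self._slice_zero, self.names_zero)

    def summary(self):
        out = ["Zero-inflated negative binomial count model",
               "=" * 48,
               f"n = {self.nobs}   log-likelihood = {self.llf:.3f}   "
               f"AIC = {self.aic:.2f}",
               f"dispersion theta = {self.theta:.3f}",
               "", "Count part (log link, offset log effort):",
               self.count_table.round(4).to_string()]
        if self.names_zero:
            out += ["", "Zero part (logit link, offset log 1/effort):",
                    self.zero_table.round(4).to_string()]
        if not self.converged:
            out += ["", "WARNING: optimizer did not report convergence"]
        return "\n".join(out)


class ZeroInflatedNestCounts:
    """ZINB model with fixed offsets in both parts.

    Parameters
    ----------
    counts : array of non-negative integers
    exog_count, exog_zero : DataFrames (or arrays) of regressors, each
        including its own intercept column.
    offset_count, offset_zero : per-unit fixed offsets on the linear scale
        of each part (log effort and log 1/effort, typically).
    """

    def __init__(self, counts, exog_count, exog_zero=None,
                 offset_count=None, offset_zero=None):
        self.y = np.asarray(counts, dtype=float)
        if np.any(self.y < 0) or np.any(self.y != np.round(self.y)):
            raise ValueError("counts must be non-negative integers")
        self.Xc = pd.DataFrame(exog_count)
        if exog_zero is None:
            exog_zero = pd.DataFrame({"const": np.ones(len(self.y))})
        self.Xz = pd.DataFrame(exog_zero)
        n = len(self.y)
        if len(self.Xc) != n or len(self.Xz) != n:
            raise ValueError("design matrices do not match counts")
        self.off_c = np.zeros(n) if offset_count is None \
            else np.asarray(offset_count, dtype=float)
        self.off_z = np.zeros(n) if offset_zero is None \
            else np.asarray(offset_zero, dtype=float)
        self._xc = self.Xc.to_numpy(dtype=float)
        self._xz = self.Xz.to_numpy(dtype=float)
        self._zero_mask = self.y == 0

    @property
    def k_params(self):
        return self._xz.shape[1] + self._xc.shape[1] + 1

    def _unpack(self, params):
        kz = self._xz.shape[1]
        kc = self._xc.shape[1]
        return params[:kz], params[kz:kz + kc], params[kz + kc]

    def loglike(self, params):
        gamma, beta, ln_alpha = self._unpack(np.asarray(params, dtype=float))
        alpha = np.exp(np.clip(ln_alpha, -30, 30))
        eta_c = np.clip(self._xc @ beta + self.off_c, -30, 30)
        mu = np.exp(eta_c)
        h = np.clip(self._xz @ gamma + self.off_z, -500, 500)
        nb_ll = _nb2_logpmf(self.y, mu, alpha)
        softplus_h = np.logaddexp(0.0, h)
        ll = np.where(
            self._zero_mask,
            np.logaddexp(h, nb_ll) - softplus_h,
            -softplus_h + nb_ll,
        )
        return float(np.sum(ll))

    def _start_params(self):
        kz = self._xz.shape[1]
        kc = self._xc.shape[1]
        start = np.zeros(self.k_params)
        mean_rate = max(self.y.mean() / np.exp(self.off_c).mean(), 1e-3)
        start[kz] = np.log(mean_rate)       # count intercept (first column)
        start[0] = -2.0                     # modest zero inflation
        return start

    def fit(self, start_params=None, compute_se=True):
        x0 = self._start_params() if start_params is None else np.asarray(start_params)
        neg = lambda p: -self.loglike(p)
        res = optimize.minimize(neg, x0, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        best = res
        # polish / rescue with a simplex pass when gradient descent stalls
        res2 = optimize.minimize(neg, best.x, method="Nelder-Mead",
                                 options={"xatol": 1e-8, "fatol": 1e-10,
                                          "maxiter": 4000})
        if res2.fun < best.fun:
            best = res2
        cov = None
        if compute_se:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hess = approx_hess(best.x, self.loglike)
                cov = np.linalg.inv(-hess)
                if not np.all(np.isfinite(np.diag(cov))) or np.any(np.diag(cov) <= 0):
                    cov = None
            except np.linalg.LinAlgError:
                cov = None
        return CountModelResult(
            best.x, list(self.Xc.columns), list(self.Xz.columns),
            llf=-best.fun, nobs=len(self.y), model=self, cov=cov,
            converged=bool(res.success or res2.success))

    def fitted_mean(self, result):
        """Unconditional fitted mean E[y] = (1 - pi) mu."""
        gamma, beta, _ = self._unpack(result.params)
        mu = np.exp(np.clip(self._xc @ beta + self.off_c, -30, 30))
        pi = special.expit(self._xz @ gamma + self.off_z)
        return (1 - pi) * mu

    def response_residuals(self, result):
        return self.y - self.fitted_mean(result)


# ----------------------------------------------------------------------
# convenience layer over transect-count tables
# ----------------------------------------------------------------------

def _year_design(year, reference=None):
    year = pd.Series(year).astype(str)
    levels = sorted(year.unique())
    if reference is None:
        reference = levels[0]
    reference = str(reference)
    if reference not in levels:
        raise ValueError(f"unknown reference level {reference!r}")
    cols = {"const": np.ones(len(year))}
    for lev in levels:
        if lev != reference:
            cols[f"year[{lev}]"] = (year == lev).astype(float).to_numpy()
    return pd.DataFrame(cols)


def fit_zinb(counts, year, length_km, autocov=None, reference=None,
             year_in_count=True, year_in_zero=True, compute_se=True):
    """Fit the transect-count ZINB with effort offsets.

    ``year`` is treated as categorical with ``reference`` in the intercept;
    ``autocov`` (if given) joins the count part only.
    """
    length_km = np.asarray(length_km, dtype=float)
    if np.any(length_km <= 0):
        raise ValueError("transect lengths must be positive")
    base = _year_design(year, reference)
    Xc = base if year_in_count else base[["const"]]
    Xz = base if year_in_zero else base[["const"]]
    Xc = Xc.copy()
    if autocov is not None:
        Xc["ac_term"] = np.asarray(autocov, dtype=float)
    model = ZeroInflatedNestCounts(
        counts, Xc, Xz,
        offset_count=np.log(length_km), offset_zero=np.log(1.0 / length_km))
    return model.fit(compute_se=compute_se)


def build_autocovariate(locations, residuals, sd_km, transect_ids=None):
    """Spatial Gaussian-kernel autocovariate over transect midpoints.

    With ``transect_ids`` given, repeat surveys of the same transect
    (inter-year distance zero) are excluded from each other's average, so
    the term really is the average over *other* transects.
    """
    return kernels.autocovariate(locations, residuals, sd_km,
                                 exclude_groups=transect_ids)


def optimize_bandwidth(counts, year, length_km, locations, sd_grid=None,
                       reference=None, refine=True, compute_se=True,
                       transect_ids=None):
    """Profile the full-model likelihood over the kernel bandwidth.

    One pass: residuals come from the full model *without* the
    autocovariate; for each candidate sd the autocovariate is built from
    those residuals and the model refitted with it; the sd maximizing the
    refitted likelihood wins.  Returns ``(sd_star, best_fit, profile)``.
    """
    if sd_grid is None:
        sd_grid = np.geomspace(0.1, 20.0, 25)
    sd_grid = np.asarray(sd_grid, dtype=float)
    if np.any(sd_grid <= 0):
        raise ValueError("bandwidths must be positive")
    base = fit_zinb(counts, year, length_km, reference=reference,
                    compute_se=False)
    resid = base.model.response_residuals(base)

    def fit_at(sd):
        ac = build_autocovariate(locations, resid, sd, transect_ids)
        return fit_zinb(counts, year, length_km, autocov=ac,
                        reference=reference, compute_se=False)

    lls, fits = [], []
    for sd in sd_grid:
        try:
            f = fit_at(sd)
            fits.append(f)
            lls.append(f.llf)
        except Exception:
            fits.append(None)
            lls.append(-np.inf)
    if not np.any(np.isfinite(lls)):
        raise RuntimeError("no bandwidth candidate could be fitted")
    i = int(np.argmax(lls))
    sd_star = float(sd_grid[i])
    if refine and len(sd_grid) >= 3 and 0 < i < len(sd_grid) - 1:
        lo, hi = sd_grid[i - 1], sd_grid[i + 1]
        try:
            r = optimize.minimize_scalar(
                lambda s: -fit_at(s).llf, bounds=(lo, hi), method="bounded",
                options={"xatol": max(1e-3, 1e-3 * sd_star)})
            if -r.fun > lls[i]:
                sd_star = float(r.x)
        except Exception:
            pass
    ac = build_autocovariate(locations, resid, sd_star, transect_ids)
    best = fit_zinb(counts, year, length_km, autocov=ac,
                    reference=reference, compute_se=compute_se)
    profile = pd.DataFrame({"sd_km": sd_grid, "loglik": lls})
    return sd_star, best, profile


def lr_test(full, reduced):
    """Likelihood-ratio test of nested count models -> (chi2, df, p)."""
    chi2 = 2.0 * (full.llf - reduced.llf)
    df = full.k_params - reduced.k_params
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    if chi2 < -1e-6:
        warnings.warn("full model fits worse than reduced: likely a local "
                      "optimum; consider refitting with new start values")
    chi2 = max(chi2, 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def relevel_year(counts, year, length_km, new_reference, autocov=None,
                 compute_se=True):
    """Refit with a new reference year; fitted values/loglik are invariant."""
    return fit_zinb(counts, year, length_km, autocov=autocov,
                    reference=new_reference, compute_se=compute_se)


def jackknife_influence(counts, year, length_km, autocov=None, reference=None):
    """Leave-one-out coefficient deltas for the count part.

    Refits the model excluding each transect in turn and reports the change
    in every count-part coefficient; failed refits are recorded as NaN rows.
    """
    counts = np.asarray(counts)
    year = np.asarray(year)
    length_km = np.asarray(length_km, dtype=float)
    n = len(counts)
    if n < 3:
        raise ValueError("jackknife needs at least three units")
    full = fit_zinb(counts, year, length_km, autocov=autocov,
                    reference=reference, compute_se=False)
    ref = full.count_params
    rows = []
    for i in range(n):
        keep = np.arange(n) != i
        try:
            ac_i = None if autocov is None else np.asarray(autocov)[keep]
            fit_i = fit_zinb(counts[keep], year[keep], length_km[keep],
                             autocov=ac_i, reference=reference,
                             compute_se=False)
            delta = fit_i.count_params.reindex(ref.index) - ref
        except Exception:
            delta = pd.Series(np.nan, index=ref.index)
        rows.append(delta)
    out = pd.DataFrame(rows, index=pd.RangeIndex(n, name="left_out"))
    return out.add_prefix("delta_")
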