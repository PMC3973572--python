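"""Gaussian-kernel autocovariates.

An autocovariate is a derived regressor that absorbs residual spatial or
temporal autocorrelation: for unit *i* it is the weighted average of the
model residuals of all *other* units, with weights following the shape of a
zero-mean Gaussian in inter-unit distance,

    ac_i = sum_{j != i} K(d_ij; sd) r_j / sum_{j != i} K(d_ij; sd),
    K(d; sd) = exp(-d^2 / (2 sd^2)).

The kernel normalising constant cancels in the weighted mean, so only the
standard deviation matters.  The same machinery serves the spatial (km),
temporal (days) and product spatio-temporal cases.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gaussian_kernel",
    "pairwise_distances",
    "autocovariate",
    "spatiotemporal_autocovariate",
]


def gaussian_kernel(d, sd):
    """Unnormalised Gaussian weight exp(-d^2 / (2 sd^2))."""
    if sd <= 0:
        raise ValueError("kernel sd must be positive")
    d = np.asarray(d, dtype=float)
    return np.exp(-0.5 * (d / sd) ** 2)


def pairwise_distances(x):
    """Euclidean distance matrix for points given as (n,) or (n, k) array."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _weighted_residual_average(weights, residuals):
    n = weights.shape[0]
    w = weights.copy()
    np.fill_diagonal(w, 0.0)  # self is always excluded
    denom = w.sum(axis=1)
    num = w @ np.asarray(residuals, dtype=float)
    out = np.zeros(n)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    if not ok.all():
        # isolated units (all weights underflow): no information, use 0
        out[~ok] = 0.0
    return out


def autocovariate(locations, residuals, sd, exclude_groups=None):
    """Kernel-weighted average of other units' residuals.

    Parameters
    ----------
    locations : array-like, shape (n,) or (n, k)
        Unit coordinates (planar km for transects, days for dates).
    residuals : array-like, shape (n,)
        Residuals of the model without the autocovariate.
    sd : float
        Gaussian kernel standard deviation, same units as ``locations``.
    exclude_groups : array-like, optional
        Group labels (e.g. transect ids): units sharing a label are
        mutually excluded, so repeat surveys of the same transect never
        average each other ("all *other* transects").  The unit itself is
        always excluded.
    """
    residuals = np.asarray(residuals, dtype=float)
    d = pairwise_distances(locations)
    if d.shape[0] < 2:
        raise ValueError("autocovariate needs at least two units")
    if len(residuals) != d.shape[0]:
        raise ValueError("locations and residuals differ in length")
    w = gaussian_kernel(d, sd)
    if exclude_groups is not None:
        g = np.asarray(exclude_groups)
        w = w * (g[:, None] != g[None, :])
    return _weighted_residual_average(w, residuals)


def spatiotemporal_autocovariate(locations, days, residuals, sd_spatial, sd_temporal):
    """Product-kernel autocovariate over space (km) and time (days).

    Weights are K_s(d_ij) * K_t(|t_i - t_j|); as ``sd_temporal`` grows the
    temporal factor tends to 1 and the purely spatial autocovariate is
    recovered.
    """
    residuals = np.asarray(residuals, dtype=float)
    ds = pairwise_distances(locations)
    dt = pairwise_distances(np.asarray(days, dtype=float))
    if ds.shape[0] < 2:
        raise ValueError("autocovariate needs at least two units")
    w = gaussian_kernel(ds, sd_spatial) * gaussian_kernel(dt, sd_temporal)
    return _weighted_residual_average(w, residuals)
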