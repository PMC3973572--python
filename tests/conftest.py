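import numpy as np
import pandas as pd
import pytest

from nestmosaic import synthdata


@pytest.fixture(scope="session")
def decay_histories():
    """Moderate revisit table from the default logistic decay parameters."""
    return synthdata.simulate_decay_histories(n_nests=200, seed=42)


@pytest.fixture(scope="session")
def halfnormal_distances():
    """Detections from a uniform nest field thinned by a half-normal
    (sigma = 12 m) within a 35 m strip."""
    rng = np.random.default_rng(7)
    x = rng.uniform(0, 35, 30000)
    return x[rng.random(len(x)) < np.exp(-0.5 * (x / 12.0) ** 2)]


@pytest.fixture(scope="session")
def transect_counts():
    """Small ZINB transect-count dataset with a known year effect."""
    rng = np.random.default_rng(11)
    n_t, years = 24, (2011, 2012, 2013)
    year = np.repeat(years, n_t)
    length = np.tile(rng.uniform(2.0, 6.0, n_t), len(years))
    ymid = np.tile(np.arange(n_t) * 0.5, len(years))
    b = {2011: 1.0, 2012: 0.4, 2013: 1.1}
    mu = length * np.exp([b[y] for y in year])
    pi = 1.0 / (1.0 + length)  # logit(pi) = log(1/L)
    lam = rng.gamma(2.0, mu / 2.0)
    counts = np.where(rng.random(len(mu)) < pi, 0, rng.poisson(lam))
    return pd.DataFrame({"count": counts, "year": year,
                         "length_km": length, "y_mid": ymid})
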