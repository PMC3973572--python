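"""Synthetic forest-savannah mosaic with two ape communities.

The field data behind the Malebo study are not public, so every downstream
stage is exercised on a synthetic landscape that reproduces the study
conditions: three forest strata with the published areas, west-east
transects spaced 500 m, two communities of nest-building apes depositing
clustered nesting sites (a Thomas-style process honouring the 30 m
same-site rule), half-normal detection from transects, logistic nest decay
with a ~183-day mean, sinusoidal fruit phenology with a between-forest
offset, seasonal rainfall, and village questionnaires with gender-specific
activities.

Planar coordinates are kilometres on a local projection (the study extent
is ~17 km, so geodesy is negligible).  Every generator is a pure function
of (config, seed); one master seed spawns independent per-stage streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import malebo
from .distsamp import TransectRecord

__all__ = [
    "LandscapeConfig",
    "CommunityConfig",
    "PhenologyConfig",
    "CohesionSimConfig",
    "default_landscape",
    "stage_rng",
    "simulate_survey",
    "simulate_decay_histories",
    "simulate_phenology",
    "simulate_questionnaire",
    "simulate_rainfall",
    "simulate_tree_plots",
    "simulate_nesting_sites",
]

_STAGE_IDS = {
    "survey": 1, "decay": 2, "phenology": 3, "questionnaire": 4,
    "rainfall": 5, "trees": 6, "sites": 7,
}


def stage_rng(seed, stage):
    """Independent RNG stream for a pipeline stage under one master seed."""
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(_STAGE_IDS.get(stage, 0),)))


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

@dataclass
class LandscapeConfig:
    """Planar landscape: rectangular forest strata plus villages.

    Rectangles are (x0, x1, y0, y1) in km, sized to the published stratum
    areas; villages are (name, (x_km, y_km), n_men, n_women).
    """

    forest_polygons: dict = None
    village_list: list = None
    transect_spacing_km: float = malebo.TRANSECT_SPACING_KM

    def __post_init__(self):
        if self.forest_polygons is None:
            self.forest_polygons = {
                "Nkala": (0.0, 5.0, 0.0, malebo.STRATUM_AREAS_KM2["Nkala"] / 5.0),
                "Mpelu": (6.0, 11.0, 0.0, malebo.STRATUM_AREAS_KM2["Mpelu"] / 5.0),
                "Lokoso&Mankere": (12.0, 13.0, 0.0,
                                   malebo.STRATUM_AREAS_KM2["Lokoso&Mankere"]),
            }
        if self.village_list is None:
            vf = malebo.village_frame()
            ys = np.linspace(0.0, 10.0, len(vf))
            self.village_list = [
                (r["village"], (-1.5, float(y)), int(r["men"]), int(r["women"]))
                for (_, r), y in zip(vf.iterrows(), ys)
            ]
        labels = list(self.forest_polygons)
        if len(set(labels)) != len(labels):
            raise ValueError("stratum labels must be unique")
        for lab, (x0, x1, y0, y1) in self.forest_polygons.items():
            if x1 <= x0 or y1 <= y0:
                raise ValueError(f"stratum {lab}: degenerate rectangle")

    @property
    def stratum_areas_km2(self):
        return {lab: (x1 - x0) * (y1 - y0)
                for lab, (x0, x1, y0, y1) in self.forest_polygons.items()}

    def transects(self, stratum):
        """West-east transects spaced ``transect_spacing_km`` apart."""
        x0, x1, y0, y1 = self.forest_polygons[stratum]
        ys = np.arange(y0 + self.transect_spacing_km / 2, y1,
                       self.transect_spacing_km)
        return [(f"{stratum}-{i:02d}", y, x0, x1) for i, y in enumerate(ys)]


#: default nest-building community sizes per (forest, year) — the study's
#: abundance estimates times the 0.75 builder fraction, rounded.
DEFAULT_BUILDERS = {
    ("Nkala", 2011): 15, ("Nkala", 2012): 12, ("Nkala", 2013): 13,
    ("Mpelu", 2011): 23, ("Mpelu", 2012): 8, ("Mpelu", 2013): 13,
}


@dataclass
class CommunityConfig:
    """Nest deposition by the communities."""

    n_builders_per_year: dict = field(
        default_factory=lambda: dict(DEFAULT_BUILDERS))
    nest_rate_per_day: float = malebo.NEST_CONSTRUCTION_RATE
    builder_fraction: float = malebo.BUILDER_FRACTION
    mean_decay_days: float = malebo.MEAN_DECAY_DAYS
    site_cluster_radius_m: float = 30.0
    mean_site_size: float = 8.0   # mean nests per nesting site

    def __post_init__(self):
        if not (0 < self.builder_fraction <= 1):
            raise ValueError("builder_fraction must be in (0, 1]")
        if self.nest_rate_per_day <= 0:
            raise ValueError("nest rate must be positive")
        if self.site_cluster_radius_m > 30.0 + 1e-9:
            raise ValueError("cluster radius exceeds the 30 m same-site rule")


@dataclass
class PhenologyConfig:
    """Sinusoidal fruiting phenology with a between-forest offset."""

    amplitude: float = 0.15        # index units (proportion scale)
    phase: float = 0.8             # radians
    forest_offset: float = 0.10    # Nkala minus Mpelu, proportion scale
    mean_level: float = 0.30       # baseline fruiting proportion
    noise_sd: float = 0.04
    period_days: float = 365.25

    def __post_init__(self):
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")

    def proportion(self, dates, forest, rng=None):
        doy = pd.to_datetime(pd.Series(dates)).dt.dayofyear.to_numpy(float)
        p = (self.mean_level
             + self.amplitude * np.sin(2 * np.pi * doy / self.period_days
                                       + self.phase))
        if forest == "Nkala":
            p = p + self.forest_offset
        if rng is not None and self.noise_sd > 0:
            p = p + rng.normal(0, self.noise_sd, size=len(doy))
        return np.clip(p, 0.0, 1.0)


# ----------------------------------------------------------------------
# transect survey
# ----------------------------------------------------------------------

def simulate_survey(landscape=None, community=None, detection_sigma_m=12.0,
                    truncation_m=35.0, years=(2011, 2012, 2013), seed=0):
    """Simulate clustered nest deposition and half-normal detection.

    Returns ``(records, truth)``: a list of :class:`TransectRecord` (one
    per transect-year, holding detected perpendicular distances within
    ``truncation_m``) and a truth table of the standing nest and builder
    densities each stratum-year actually had.
    """
    if detection_sigma_m <= 0:
        raise ValueError("detection sigma must be positive")
    landscape = landscape or LandscapeConfig()
    community = community or CommunityConfig()
    rng = stage_rng(seed, "survey")
    if not landscape.forest_polygons:
        raise ValueError("empty landscape")

    records, truth_rows = [], []
    areas = landscape.stratum_areas_km2
    for stratum in landscape.forest_polygons:
        transects = landscape.transects(stratum)
        if not transects:
            raise ValueError(f"stratum {stratum}: no transects fit")
        x0, x1, y0, y1 = landscape.forest_polygons[stratum]
        for year in years:
            n_builders = community.n_builders_per_year.get((stratum, year), 0)
            expected_nests = (n_builders * community.nest_rate_per_day
                              * community.mean_decay_days)
            xs, ys = _thomas_nests(rng, expected_nests, (x0, x1, y0, y1),
                                   community)
            truth_rows.append({
                "stratum": stratum, "year": year,
                "n_builders": n_builders,
                "builder_density_km2": n_builders / areas[stratum],
                "n_nests": len(xs),
                "nest_density_km2": len(xs) / areas[stratum],
            })
            for tid, ty, tx0, tx1 in transects:
                on_line = (xs >= tx0) & (xs <= tx1)
                d_m = np.abs(ys[on_line] - ty) * 1000.0
                d_m = d_m[d_m <= truncation_m]
                if np.isfinite(detection_sigma_m):
                    p_det = np.exp(-0.5 * (d_m / detection_sigma_m) ** 2)
                else:
                    p_det = np.ones_like(d_m)
                kept = d_m[rng.random(len(d_m)) < p_det]
                records.append(TransectRecord(
                    transect_id=tid, stratum=stratum, year=year,
                    length_km=tx1 - tx0, distances_m=sorted(kept.tolist())))
    return records, pd.DataFrame(truth_rows)


def _thomas_nests(rng, expected_nests, rect, community):
    """Thomas-style cluster process: parents are sites, offspring nests."""
    x0, x1, y0, y1 = rect
    if expected_nests <= 0:
        return np.array([]), np.array([])
    n_sites = rng.poisson(expected_nests / community.mean_site_size)
    xs, ys = [], []
    r_km = community.site_cluster_radius_m / 2000.0  # radius/2 in km
    for _ in range(n_sites):
        cx = rng.uniform(x0, x1)
        cy = rng.uniform(y0, y1)
        size = max(1, rng.poisson(community.mean_site_size))
        ang = rng.uniform(0, 2 * np.pi, size)
        rad = r_km * np.sqrt(rng.uniform(0, 1, size))
        xs.append(cx + rad * np.cos(ang))
        ys.append(cy + rad * np.sin(ang))
    if not xs:
        return np.array([]), np.array([])
    return np.concatenate(xs), np.concatenate(ys)


def survey_to_frames(records):
    """Split TransectRecords into transect and detection tables (CSV-ready)."""
    trans = pd.DataFrame([{
        "transect_id": r.transect_id, "stratum": r.stratum, "year": r.year,
        "length_km": r.length_km} for r in records])
    det = pd.DataFrame([
        {"transect_id": r.transect_id, "stratum": r.stratum, "year": r.year,
         "distance_m": d}
        for r in records for d in r.distances_m])
    return trans, det


def frames_to_records(transects, detections):
    """Rebuild TransectRecords from the two CSV tables."""
    det = detections.groupby(["transect_id", "year"])["distance_m"] \
        .apply(list).to_dict()
    out = []
    for _, r in transects.iterrows():
        out.append(TransectRecord(
            transect_id=r["transect_id"], stratum=r["stratum"],
            year=int(r["year"]), length_km=float(r["length_km"]),
            distances_m=det.get((r["transect_id"], int(r["year"])), [])))
    return out


# ----------------------------------------------------------------------
# nest decay histories
# ----------------------------------------------------------------------

def simulate_decay_histories(n_nests=610, beta0=4.6, beta1=-0.025,
                             revisit_interval_days=7, n_sites=42, seed=0,
                             start="2011-08-01"):
    """Weekly revisit histories under logistic survival.

    Each nest's recognizable lifetime T satisfies P(T > t) =
    logistic(beta0 + beta1 t); revisits run every
    ``revisit_interval_days`` until the first visit at or past T, recorded
    as "disappeared" (absorbing).  Intermediate codes follow age: new
    (< 7 d), recent (< 30 d), old (< 90 d), very old.
    """
    if beta1 >= 0:
        raise ValueError("beta1 must be negative: nests must decay")
    rng = stage_rng(seed, "decay")
    start = pd.Timestamp(start)
    site_of_nest = rng.integers(0, n_sites, size=n_nests)
    site_start = {s: start + pd.Timedelta(days=int(rng.integers(0, 300)))
                  for s in range(n_sites)}
    u = rng.uniform(0, 1, size=n_nests)
    with np.errstate(divide="ignore"):
        lifetimes = np.where(u < expit(beta0),
                             (logit(u) - beta0) / beta1, 0.0)
    rows = []
    for i in range(n_nests):
        t0 = site_start[site_of_nest[i]]
        T = lifetimes[i]
        age = revisit_interval_days
        while True:
            if age >= T:
                cond = "disappeared"
            elif age < 7:
                cond = "new"
            elif age < 30:
                cond = "recent"
            elif age < 90:
                cond = "old"
            else:
                cond = "very old"
            rows.append((f"nest{i:04d}", f"site{site_of_nest[i]:03d}",
                         t0, t0 + pd.Timedelta(days=age), cond))
            if cond == "disappeared":
                break
            age += revisit_interval_days
    return pd.DataFrame(rows, columns=[
        "nest_id", "site_id", "construction_date", "visit_date", "condition"])


# ----------------------------------------------------------------------
# phenology, rainfall
# ----------------------------------------------------------------------

def simulate_phenology(phen=None, plots=None, dates=None, seed=0):
    """Biweekly fruiting observations per plot and species.

    ``plots``: DataFrame ``plot_id, forest, species, n_trees`` (defaults to
    a small two-forest layout); ``dates``: 14-day spaced visit dates.
    Proportions follow the sinusoid + forest offset + noise, clipped to
    [0, 1]; the observed fruiting count is the rounded proportion of the
    plot's trees, so a zero-noise configuration is exactly periodic.
    """
    phen = phen or PhenologyConfig()
    rng = stage_rng(seed, "phenology")
    if plots is None:
        plots = default_fruiting_plots()
    if dates is None:
        dates = pd.date_range("2011-05-01", "2013-05-01", freq="14D")
    dates = pd.DatetimeIndex(dates)
    if len(dates) > 1:
        gaps = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if not np.all(gaps == 14):
            raise ValueError("fruiting visits must be 14 days apart")
    rows = []
    for _, p in plots.iterrows():
        props = phen.proportion(dates, p["forest"],
                                rng if phen.noise_sd > 0 else None)
        n_fruiting = np.rint(props * p["n_trees"]).astype(int)
        for d, nf in zip(dates, n_fruiting):
            rows.append((p["plot_id"], p["forest"], p["species"], d,
                         int(p["n_trees"]), int(nf)))
    out = pd.DataFrame(rows, columns=[
        "plot_id", "forest", "species", "date", "n_trees", "n_fruiting"])
    out["proportion"] = np.where(out["n_trees"] > 0,
                                 out["n_fruiting"] / out["n_trees"], 0.0)
    return out


def default_fruiting_plots(n_species=12, trees_per_species=6):
    rows = []
    for forest, n_plots in (("Nkala", 3), ("Mpelu", 3)):
        for k in range(n_plots):
            for s in range(n_species):
                rows.append((f"{forest}-p{k}", forest, f"sp{s:02d}",
                             trees_per_species))
    return pd.DataFrame(rows, columns=["plot_id", "forest", "species",
                                       "n_trees"])


def simulate_rainfall(start="2011-05-01", end="2013-06-30", seed=0,
                      mean_annual_mm=1550.0):
    """Daily rainfall with the two regional dry seasons (Feb, Jul-Aug)."""
    rng = stage_rng(seed, "rainfall")
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy(float)
    dry = (np.exp(-0.5 * ((doy - 45) / 18) ** 2)
           + np.exp(-0.5 * ((doy - 210) / 25) ** 2))
    p_wet = np.clip(0.55 * (1.0 - 0.85 * dry), 0.02, 1.0)
    wet = rng.random(len(dates)) < p_wet
    shape, target_daily = 0.9, mean_annual_mm / 365.25
    scale = target_daily / (p_wet.mean() * shape)
    amounts = np.where(wet, rng.gamma(shape, scale, size=len(dates)), 0.0)
    return pd.Series(amounts, index=dates, name="rain_mm")


# ----------------------------------------------------------------------
# tree plots and questionnaires
# ----------------------------------------------------------------------

def simulate_tree_plots(landscape=None, n_species=30, stems_per_ha=360.0,
                        seed=0):
    """Stem table of the tree-abundance plot survey.

    Species abundances follow a geometric rank-abundance curve; DBH is
    lognormal above the 10 cm inclusion threshold.  Returns ``(trees,
    plot_areas)`` where plot_areas maps forest -> sampled hectares.
    """
    landscape = landscape or LandscapeConfig()
    rng = stage_rng(seed, "trees")
    species = [f"sp{k:02d}" for k in range(n_species)]
    ranks = np.arange(n_species)
    p = 0.85**ranks
    p /= p.sum()
    plot_areas = {"Nkala": 11.25, "Mpelu": 14.25}
    rows = []
    for forest, ha in plot_areas.items():
        n = rng.poisson(stems_per_ha * ha)
        sp = rng.choice(species, size=n, p=p)
        dbh = 10.0 + rng.lognormal(mean=2.5, sigma=0.8, size=n)
        rows.append(pd.DataFrame({
            "plot_id": f"{forest}-abund", "forest": forest,
            "species": sp, "dbh_cm": dbh}))
    return pd.concat(rows, ignore_index=True), plot_areas


def simulate_questionnaire(villages=None, activities=None, seed=0,
                           regions=("Nkala", "Mpelu", "Lokoso&Mankere")):
    """Per-person activity frequencies and visited forest regions.

    ``villages`` defaults to the published census; ``activities`` maps
    activity -> (gender, census interview-count column).  Gender-specific
    activities never draw on the other gender (hunting is men-only,
    fish-scooping women-only).
    """
    rng = stage_rng(seed, "questionnaire")
    if villages is None:
        villages = malebo.village_frame()
    if activities is None:
        activities = {
            "hunting": ("M", "hunters_m"),
            "fishing_m": ("M", "fishers_m"),
            "fishing_w": ("W", "fishers_w"),
            "ntpc_m": ("M", "ntpc_m"),
            "ntpc_w": ("W", "ntpc_w"),
        }
    if len(villages) == 0:
        raise ValueError("need at least one village")
    freqs = np.array([1.0, 0.5, 1.0 / 7.0])
    freq_p = np.array([0.3, 0.4, 0.3])
    rows = []
    pid = 0
    for _, v in villages.iterrows():
        for act, (gender, col) in activities.items():
            for _ in range(int(v[col])):
                n_reg = rng.integers(1, len(regions) + 1)
                visited = rng.choice(regions, size=n_reg, replace=False)
                rows.append((v["village"], act, gender, f"p{pid:04d}",
                             float(rng.choice(freqs, p=freq_p)),
                             ";".join(sorted(visited))))
                pid += 1
    return pd.DataFrame(rows, columns=[
        "village", "activity", "gender", "person_id", "freq_per_day",
        "regions"])


# ----------------------------------------------------------------------
# nesting sites for the cohesion models
# ----------------------------------------------------------------------

@dataclass
class CohesionSimConfig:
    """Generator for per-site covariates and NB nest counts.

    Slopes are on the z-scale of each predictor (the scale the models
    report); the regime decides which community-size offset scales the
    mean: the site's own forest ("two") or the pooled total ("one").
    """

    n_sites: int = 90
    slopes: dict = field(default_factory=lambda: {
        "density_suitable_trees": 0.070,
        "fruit_forest_14d": 0.049,
        "fruit_site": 0.109,
        "village_influence": 0.011,
        "human_forest_use": 0.045,
        "rainfall_30d": -0.016,
    })
    intercept: float = 0.0
    nb_alpha: float = 0.06
    regime: str = "two"           # "two" or "one" community data
    start: str = "2011-05-15"
    end: str = "2013-05-01"


def _interp_builders(community, forest, when):
    """Linear interpolation of the yearly builder estimates (mid-year knots)."""
    years = sorted({y for (f, y) in community.n_builders_per_year if f == forest})
    knots = [(pd.Timestamp(f"{y}-07-01"),
              community.n_builders_per_year[(forest, y)]) for y in years]
    t = pd.Timestamp(when)
    if t <= knots[0][0]:
        return float(knots[0][1])
    if t >= knots[-1][0]:
        return float(knots[-1][1])
    for (d0, s0), (d1, s1) in zip(knots, knots[1:]):
        if d0 <= t <= d1:
            w = (t - d0) / (d1 - d0)
            return float((1 - w) * s0 + w * s1)
    raise RuntimeError("unreachable")


def simulate_nesting_sites(landscape=None, community=None, phen=None,
                           config=None, rain=None, seed=0):
    """Per-site covariates, offsets and NB nest counts.

    Returns a DataFrame with one row per nesting site: location, forest,
    date, the six raw predictors, the two candidate offsets
    (``builders_forest``, ``builders_total``) and ``nest_count`` drawn from
    the configured regime's NB model (zero counts resampled: a recorded
    site has at least one nest).
    """
    landscape = landscape or LandscapeConfig()
    community = community or CommunityConfig()
    phen = phen or PhenologyConfig()
    config = config or CohesionSimConfig()
    rng = stage_rng(seed, "sites")
    if rain is None:
        rain = simulate_rainfall(seed=seed)

    forests = ["Nkala", "Mpelu"]
    dates = pd.to_datetime(
        rng.integers(pd.Timestamp(config.start).value // 10**9,
                     pd.Timestamp(config.end).value // 10**9,
                     size=config.n_sites), unit="s").normalize()
    rows = []
    for i in range(config.n_sites):
        forest = forests[int(rng.random() < 0.5)]
        x0, x1, y0, y1 = landscape.forest_polygons[forest]
        x, y = rng.uniform(x0, x1), rng.uniform(y0, y1)
        date = dates[i]
        b_forest = _interp_builders(community, forest, date)
        b_total = sum(_interp_builders(community, f, date) for f in forests)
        fruit_forest = float(phen.proportion([date], forest)[0]) * 20.0 \
            + rng.normal(0, 0.5)
        mask = (rain.index >= date - pd.Timedelta(days=30)) & (rain.index < date)
        rows.append({
            "site_id": f"ns{i:03d}", "date_built": date, "forest": forest,
            "x_km": x, "y_km": y,
            "density_suitable_trees": rng.gamma(4.0, 25.0),
            "fruit_forest_14d": max(fruit_forest, 0.05),
            "fruit_site": rng.gamma(2.0, 0.8),
            "village_influence": 0.0,   # filled from geometry below
            "human_forest_use": rng.lognormal(1.0, 0.6),
            "rainfall_30d": float(rain[mask].sum()),
            "builders_forest": b_forest, "builders_total": b_total,
        })
    df = pd.DataFrame(rows)
    from .covariates import village_influence as _vi

    vils = [(m + w, loc) for (_, loc, m, w) in landscape.village_list]
    df["village_influence"] = [
        _vi((r["x_km"], r["y_km"]), vils) for _, r in df.iterrows()]

    z = {}
    for p in config.slopes:
        x = df[p].to_numpy(float)
        if p == "human_forest_use":
            x = np.log(x)
        z[p] = (x - x.mean()) / x.std(ddof=1)
    lp = config.intercept + sum(config.slopes[p] * z[p] for p in config.slopes)
    offset = df["builders_forest"] if config.regime == "two" \
        else df["builders_total"]
    mu = offset.to_numpy(float) * np.exp(lp)
    df["nest_count"] = _nb_positive(rng, mu, config.nb_alpha)
    return df


def _nb_positive(rng, mu, alpha, max_tries=200):
    """NB2 draws conditioned on being >= 1 (a site implies >= 1 nest)."""
    r = 1.0 / alpha
    out = np.zeros(len(mu), dtype=int)
    todo = np.ones(len(mu), dtype=bool)
    for _ in range(max_tries):
        if not todo.any():
            break
        lam = rng.gamma(r, np.asarray(mu)[todo] * alpha)
        draw = rng.poisson(lam)
        out[np.flatnonzero(todo)[draw > 0]] = draw[draw > 0]
        nxt = todo.copy()
        nxt[np.flatnonzero(todo)[draw > 0]] = False
        todo = nxt
    out[todo] = 1
    return out


def default_landscape():
    """The default study landscape (published areas, census villages)."""
    return LandscapeConfig()
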