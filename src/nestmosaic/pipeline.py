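"""End-to-end orchestration of the nest-survey pipeline.

Stages run in dependency order — synthetic data, nest decay, distance
sampling densities, between-year dynamics, fruit phenology, site
covariates, cohesion models — each reading and writing plain CSV tables
under the configured output directory, so partial reruns just re-point at
an existing directory.  Every stage is a pure function of (inputs, seed);
rerunning with the same seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohesion, covariates, decay, distsamp, dynamics, malebo
from . import phenology as phen_mod
from . import synthdata

log = logging.getLogger("nestmosaic")

__all__ = ["PipelineConfig", "run_pipeline", "validate_tables"]


@dataclass
class PipelineConfig:
    """Constants, seeds and paths of one pipeline run."""

    out_dir: str = "nestmosaic_out"
    seed: int = 0
    nest_rate: float = malebo.NEST_CONSTRUCTION_RATE
    builder_fraction: float = malebo.BUILDER_FRACTION
    truncation_prob: float = malebo.DETECTION_P_THRESHOLD
    alpha: float = 0.05
    n_boot: int = 1000
    n_perm: int = 10000
    detection_sigma_m: float = 12.0
    max_truncation_m: float = 35.0
    sd_grid_km: tuple = (0.3, 0.7, 1.5, 3.0, 6.0)
    ac_grid_s_km: tuple = (0.5, 2.0, 8.0)
    ac_grid_t_days: tuple = (10.0, 40.0, 120.0)

    def __post_init__(self):
        for name in ("nest_rate", "builder_fraction", "truncation_prob",
                     "alpha", "n_boot", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ----------------------------------------------------------------------
# schema validation
# ----------------------------------------------------------------------

SCHEMAS = {
    "transects": {
        "columns": ["transect_id", "stratum", "year", "length_km"],
        "checks": [("length_km", lambda s: (s > 0).all(),
                    "transect lengths must be positive")],
    },
    "detections": {
        "columns": ["transect_id", "stratum", "year", "distance_m"],
        "checks": [("distance_m", lambda s: (s >= 0).all(),
                    "perpendicular distances must be non-negative")],
    },
    "decay_histories": {
        "columns": ["nest_id", "site_id", "construction_date", "visit_date",
                    "condition"],
        "checks": [("condition",
                    lambda s: s.isin(decay.CONDITIONS).all(),
                    "unknown nest condition code")],
    },
    "fruiting": {
        "columns": ["plot_id", "forest", "species", "date", "n_trees",
                    "n_fruiting"],
        "checks": [("n_fruiting", lambda s: (s >= 0).all(),
                    "fruiting counts must be non-negative")],
    },
    "rainfall": {
        "columns": ["date", "rain_mm"],
        "checks": [("rain_mm", lambda s: (s >= 0).all(),
                    "rainfall must be non-negative")],
    },
    "questionnaire": {
        "columns": ["village", "activity", "gender", "person_id",
                    "freq_per_day", "regions"],
        "checks": [("freq_per_day", lambda s: (s > 0).all(),
                    "activity frequencies must be positive")],
    },
    "sites": {
        "columns": ["site_id", "date_built", "forest", "x_km", "y_km",
                    "nest_count", "builders_forest", "builders_total"],
        "checks": [("nest_count", lambda s: (s >= 1).all(),
                    "a nesting site has at least one nest")],
    },
}


def validate_tables(tables):
    """Check CSV tables against the pipeline schemas.

    ``tables`` maps schema name -> DataFrame or path.  Returns a list of
    error strings (empty when clean).
    """
    errors = []
    for name, obj in tables.items():
        schema = SCHEMAS.get(name)
        if schema is None:
            errors.append(f"{name}: unknown table")
            continue
        df = pd.read_csv(obj) if not isinstance(obj, pd.DataFrame) else obj
        missing = [c for c in schema["columns"] if c not in df.columns]
        if missing:
            errors.append(f"{name}: missing columns {missing}")
            continue
        for col, check, msg in schema["checks"]:
            try:
                ok = bool(check(df[col]))
            except Exception as exc:  # dtype problems surface here
                errors.append(f"{name}.{col}: {exc}")
                continue
            if not ok:
                errors.append(f"{name}.{col}: {msg}")
    return errors


def _write(df, path):
    df.to_csv(path, index=False)
    return path


def _sha(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def stage_simulate(cfg, out):
    landscape = synthdata.LandscapeConfig()
    community = synthdata.CommunityConfig(
        nest_rate_per_day=cfg.nest_rate, builder_fraction=cfg.builder_fraction)
    records, truth = synthdata.simulate_survey(
        landscape, community, detection_sigma_m=cfg.detection_sigma_m,
        truncation_m=cfg.max_truncation_m, seed=cfg.seed)
    trans, det = synthdata.survey_to_frames(records)
    _write(trans, out / "transects.csv")
    _write(det, out / "detections.csv")
    _write(truth, out / "survey_truth.csv")

    hist = synthdata.simulate_decay_histories(seed=cfg.seed)
    _write(hist, out / "decay_histories.csv")

    fruiting = synthdata.simulate_phenology(seed=cfg.seed)
    _write(fruiting, out / "fruiting.csv")

    rain = synthdata.simulate_rainfall(seed=cfg.seed)
    _write(rain.rename_axis("date").reset_index(), out / "rainfall.csv")

    quest = synthdata.simulate_questionnaire(seed=cfg.seed)
    _write(quest, out / "questionnaire.csv")

    trees, plot_areas = synthdata.simulate_tree_plots(landscape, seed=cfg.seed)
    _write(trees, out / "abundance_trees.csv")

    sites = synthdata.simulate_nesting_sites(
        landscape, community, rain=rain, seed=cfg.seed)
    _write(sites, out / "sites.csv")
    log.info("simulate: %d transect-years, %d nests revisited, %d sites",
             len(records), hist["nest_id"].nunique(), len(sites))
    return {"plot_areas": plot_areas}


def stage_decay(cfg, out):
    hist = pd.read_csv(out / "decay_histories.csv")
    est = decay.bootstrap_decay(hist, n_boot=cfg.n_boot, seed=cfg.seed)
    row = pd.DataFrame([{
        "beta0": est.beta0, "beta1": est.beta1,
        "mean_days": est.mean_days, "ci_low_days": est.ci_low_days,
        "ci_high_days": est.ci_high_days, "n_boot": est.n_boot}])
    _write(row, out / "decay_estimate.csv")
    log.info("decay: mean %.1f d (%.1f-%.1f)", est.mean_days,
             est.ci_low_days, est.ci_high_days)
    return est


def stage_density(cfg, out):
    trans = pd.read_csv(out / "transects.csv")
    det = pd.read_csv(out / "detections.csv")
    errors = validate_tables({"transects": trans, "detections": det})
    if errors:
        raise ValueError("; ".join(errors))
    dec = pd.read_csv(out / "decay_estimate.csv").iloc[0]
    records = synthdata.frames_to_records(trans, det)
    all_d = np.concatenate([r.distances_m for r in records
                            if r.distances_m]) if any(
        r.distances_m for r in records) else np.array([])
    w, _, fit = distsamp.truncate_by_detection(
        all_d, threshold=cfg.truncation_prob)
    decay_cv = ((dec["ci_high_days"] - dec["ci_low_days"]) /
                (2 * 1.96 * dec["mean_days"]))
    consts = distsamp.ConversionConstants(
        nest_rate=cfg.nest_rate, builder_fraction=cfg.builder_fraction,
        decay_days=float(dec["mean_days"]), decay_cv=float(decay_cv))
    areas = synthdata.LandscapeConfig().stratum_areas_km2
    per_stratum = []
    for (stratum, year), recs in _group_records(records, w):
        per_stratum.append(distsamp.density_estimate(
            recs, fit, consts, stratum=stratum, year=year,
            area_km2=areas[stratum]))
    rows = [e.as_row() for e in per_stratum]
    for year in sorted({e.year for e in per_stratum}):
        glob = distsamp.stratified_abundance(
            [e for e in per_stratum if e.year == year])
        r = glob.as_row()
        r["year"] = year
        r["stratum"] = "Global"
        rows.append(r)
    table = pd.DataFrame(rows)
    _write(table, out / "density_table.csv")
    meta = pd.DataFrame([{"truncation_w_m": w, "esw_m": fit.esw_m,
                          "p_bar": fit.p_bar, "n_used": fit.n_used}])
    _write(meta, out / "detection_fit.csv")
    log.info("density: w=%.1f m, ESW=%.2f m, p=%.3f", w, fit.esw_m, fit.p_bar)
    return table


def _group_records(records, w):
    groups = {}
    for r in records:
        kept = [d for d in r.distances_m if d <= w]
        groups.setdefault((r.stratum, r.year), []).append(
            distsamp.TransectRecord(r.transect_id, r.stratum, r.year,
                                    r.length_km, kept))
    return sorted(groups.items())


def stage_dynamics(cfg, out):
    trans = pd.read_csv(out / "transects.csv")
    det = pd.read_csv(out / "detections.csv")
    results = {}
    for forest in ("Nkala", "Mpelu"):
        t = trans[trans["stratum"] == forest].copy()
        d = det[det["stratum"] == forest]
        counts = d.groupby(["transect_id", "year"]).size()
        t["count"] = [counts.get((r["transect_id"], r["year"]), 0)
                      for _, r in t.iterrows()]
        # transect midpoint: y from its index along the stratum
        order = {tid: i for i, tid in enumerate(sorted(t["transect_id"].unique()))}
        t["y_mid"] = t["transect_id"].map(order).astype(float) * 0.5
        sd, fit, profile = dynamics.optimize_bandwidth(
            t["count"].to_numpy(), t["year"].to_numpy(),
            t["length_km"].to_numpy(), t["y_mid"].to_numpy(),
            sd_grid=np.asarray(cfg.sd_grid_km), refine=False)
        base = dynamics.fit_zinb(t["count"].to_numpy(), t["year"].to_numpy(),
                                 t["length_km"].to_numpy(), compute_se=False)
        null = dynamics.fit_zinb(
            t["count"].to_numpy(), t["year"].to_numpy(),
            t["length_km"].to_numpy(),
            autocov=fit.model.Xc["ac_term"].to_numpy(),
            year_in_count=False, year_in_zero=False, compute_se=False)
        chi2, df, p = dynamics.lr_test(fit, null)
        tab = fit.count_table.reset_index(names="term")
        tab.insert(0, "part", "count")
        ztab = fit.zero_table.reset_index(names="term")
        ztab.insert(0, "part", "zero")
        _write(pd.concat([tab, ztab]), out / f"dynamics_{forest}.csv")
        results[forest] = {"sd_km": sd, "year_lr": (chi2, df, p),
                           "fit": fit}
        log.info("dynamics %s: sd*=%.2f km, year LR chi2=%.2f (df=%d, p=%.3f)",
                 forest, sd, chi2, df, p)
    return results


def stage_phenology(cfg, out, plot_areas=None):
    fruiting = pd.read_csv(out / "fruiting.csv", parse_dates=["date"])
    trees = pd.read_csv(out / "abundance_trees.csv")
    plot_areas = plot_areas or {"Nkala": 11.25, "Mpelu": 14.25}
    ba = phen_mod.basal_area_table(trees, plot_areas, by=["forest"])
    series = phen_mod.fruit_index(fruiting, ba, by=("forest", "date"))
    series = series[series["value"] > 0]
    _write(series, out / "fruit_index.csv")
    model = phen_mod.SeasonalFruitModel(series)
    res = model.fit(ac_sd_days="optimize")
    tab = pd.DataFrame({"estimate": res.ols.params, "se": res.ols.bse,
                        "t": res.ols.tvalues, "p": res.ols.pvalues})
    tab = tab.reset_index(names="term")
    _write(tab, out / "seasonal_model.csv")
    log.info("phenology: lambda=%.2f amplitude=%.3f", res.lambda_,
             res.amplitude)
    return res


def stage_covariates(cfg, out):
    sites = pd.read_csv(out / "sites.csv", parse_dates=["date_built"])
    # the generator emits the raw site covariates; this stage validates the
    # matrix handed to the cohesion models and runs the nesting-tree
    # preference test against the plot-survey abundances
    errors = validate_tables({"sites": sites})
    if errors:
        raise ValueError("; ".join(errors))

    trees = pd.read_csv(out / "abundance_trees.csv")
    abundance = trees["species"].value_counts()
    rng = synthdata.stage_rng(cfg.seed, "sites")
    # nest trees: preference-weighted draw over the species pool (the
    # first few species are strongly preferred for nest building)
    weights = abundance.astype(float)
    weights.iloc[:5] *= 4.0
    n_nests = int(sites["nest_count"].sum())
    nest_trees = rng.choice(abundance.index, size=n_nests,
                            p=(weights / weights.sum()).to_numpy())
    counts = pd.Series(nest_trees).value_counts()
    counts = counts.reindex(abundance.index, fill_value=0)
    pref = covariates.preference_test(
        counts.to_dict(), abundance.to_dict(),
        n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha)
    rep = pref.per_species.reset_index(names="species")
    rep["preferred"] = rep["species"].isin(pref.preferred)
    _write(rep, out / "preference.csv")
    log.info("covariates: preference chi2=%.1f (perm p=%.4g), %d preferred",
             pref.chi2, pref.p_permutation, len(pref.preferred))

    _write(sites, out / "covariate_matrix.csv")
    return sites


def stage_cohesion(cfg, out):
    data = pd.read_csv(out / "covariate_matrix.csv",
                       parse_dates=["date_built"])
    fits = {}
    for hyp in ("one_community", "two_communities"):
        model = cohesion.CohesionModel(data, hypothesis=hyp)
        _, _, fit, retained, _ = cohesion.optimize_two_bandwidths(
            data, model.offset_col, grid_s=cfg.ac_grid_s_km,
            grid_t=cfg.ac_grid_t_days, drop_alpha=cfg.alpha)
        fits[hyp] = fit
        _write(fit.table.reset_index(names="term"),
               out / f"cohesion_{hyp}.csv")
    comp = cohesion.compare_hypotheses(fits["one_community"],
                                       fits["two_communities"])
    winner_fit = fits["two_communities"] if comp.winner == "two_communities" \
        else fits["one_community"]
    null = cohesion.fit_cohesion(
        data, winner_fit.offset_name, predictors=cohesion.HUMAN_CONTROLS,
        ac=getattr(winner_fit, "ac_values", None))
    comp.block_test = cohesion.environmental_block_test(winner_fit, null)
    report = {
        "aicc_model1": comp.aicc_model1, "aicc_model2": comp.aicc_model2,
        "winner": comp.winner, "delta_aicc": comp.delta,
        "environmental_block": {
            "chi2": comp.block_test[0], "df": comp.block_test[1],
            "p": comp.block_test[2]},
    }
    (out / "cohesion_report.json").write_text(json.dumps(report, indent=2))
    log.info("cohesion: %s", comp.summary().replace("\n", " | "))
    return comp


def run_pipeline(cfg=None):
    """Run every stage in order; returns a dict of stage results."""
    cfg = cfg or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    extra = stage_simulate(cfg, out)
    results["decay"] = stage_decay(cfg, out)
    results["density"] = stage_density(cfg, out)
    results["dynamics"] = stage_dynamics(cfg, out)
    results["phenology"] = stage_phenology(cfg, out,
                                           plot_areas=extra["plot_areas"])
    results["covariates"] = stage_covariates(cfg, out)
    results["cohesion"] = stage_cohesion(cfg, out)
    manifest = {p.name: _sha(p) for p in sorted(out.glob("*.csv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
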