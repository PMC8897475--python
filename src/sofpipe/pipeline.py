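"""End-to-end orchestration of the seascape-of-fear analysis.

Stages mirror the analysis design: synthetic cohort generation, gannet
track segmentation and tactic classification, colony-specific day/night
seal RSFs with leave-one-out validation, the max-overlay fearscape
rasters, the gannet daytime foraging RSF against VAR(1) null-track
availability, the diel daytime-foraging vs nighttime-resting model with
AICc form selection, and the habitat-use summary table with its derived
diel quantities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import availability, diel, fearscape, rsf, segmentation, summary
from . import trajectory, validation
from .geo_env import catch_grid_spec, rasterize_catch, resample_to_grid
from .synthetic_data import SimConfig, generate_all

logger = logging.getLogger(__name__)

SEAL_COVARIATES = ["bathymetry", "slope", "dist_colony"]
GANNET_COVARIATES = ["seal_index", "purse", "trawl"]


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    scale: str = "test"               # 'test' | 'paper'
    outdir: str | None = None
    seg_kwargs: dict = field(default_factory=lambda: {
        "Kmax": 20, "Lmin": 5, "max_iter": 5, "n_init": 4})
    n_sim_tracks: int = 10
    availability_ratio: int = 5
    weight: float = 1000.0
    sigma0_sq: float = 1e6
    run_cv: bool = True
    colony_radius_km: float = 1.0

    def sim_config(self) -> SimConfig:
        return SimConfig.test_scale() if self.scale == "test" \
            else SimConfig()


def _shore_distance(x, y):
    """Distance to the synthetic coastline (the x = 0 meridian)."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def segment_gannets(bundle, cfg: RunConfig, seed: int):
    """Derive descriptors, segment and classify every gannet trip."""
    sim_cfg: SimConfig = bundle["cfg"]
    colony_xy = sim_cfg.gannet_colony_xy
    per_fix_rows, trip_rows = [], []
    year_of = bundle["trip_truth"].set_index("trip_id")["year"].to_dict()
    for track in bundle["gannet_tracks"]:
        track_i = trajectory.reinterpolate(track)
        series = trajectory.derive_step_series(
            track_i, colony_xy=colony_xy, shore_distance=_shore_distance)
        beh = segmentation.segment_cluster(series, seed=seed,
                                           **cfg.seg_kwargs)
        tactic = segmentation.classify_tactic(
            track_i, beh, series["is_day"].to_numpy(),
            colony_xy=colony_xy, radius_km=cfg.colony_radius_km)
        series = series.copy()
        series["state"] = beh.states
        series["individual_id"] = track.individual_id
        series["trip_id"] = track.trip_id
        series["year"] = year_of.get(track.trip_id, 0)
        per_fix_rows.append(series)
        trip_rows.append({
            "trip_id": track.trip_id,
            "individual_id": track.individual_id,
            "tactic": tactic.tactic,
            "night_fraction_resting": tactic.night_fraction_resting,
            "n_night_fixes": tactic.n_night_fixes,
            "year": year_of.get(track.trip_id, 0)})
    return (pd.concat(per_fix_rows, ignore_index=True),
            pd.DataFrame(trip_rows))


def fit_seal_models(bundle, cfg: RunConfig, seed: int):
    """Colony-specific day and night seal RSFs + fearscape rasters."""
    env = bundle["env"]
    sim_cfg: SimConfig = bundle["cfg"]
    rng = np.random.default_rng(seed)
    by_colony = {}
    for track in bundle["seal_tracks"]:
        by_colony.setdefault(track.colony_name, []).append(track)

    colony_results = {}
    binned = {"day": [], "night": []}
    for ci, (cname, tracks) in enumerate(sorted(by_colony.items())):
        fixes = []
        for tr in tracks:
            df = tr.fixes[["timestamp", "x", "y", "lon", "lat"]].copy()
            df["individual_id"] = tr.individual_id
            fixes.append(df)
        fixes = pd.concat(fixes, ignore_index=True)
        elev = trajectory.solar_elevation(fixes["timestamp"],
                                          fixes["lon"], fixes["lat"])
        fixes["is_day"] = elev > 0
        ud = availability.kernel_ud(fixes[["x", "y"]].to_numpy(),
                                    env.grid, sea_mask=env.sea_mask,
                                    colony=cname)
        dist_layer = f"dist_colony_seal{ci}"
        cov_map = {"bathymetry": "bathymetry", "slope": "slope",
                   "dist_colony": dist_layer}
        colony_results[cname] = {"ud": ud, "models": {}, "cv": {}}
        for period, is_day in (("day", True), ("night", False)):
            used = fixes[fixes["is_day"] == is_day].copy()
            pts = availability.sample_available_random(
                ud, n_used=len(used), ratio=cfg.availability_ratio,
                rng=rng)
            avail = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]})
            # spread available points across individuals (each needs both)
            ids = used["individual_id"].unique()
            avail["individual_id"] = np.repeat(
                np.tile(ids, int(np.ceil(len(avail) / len(ids)))),
                1)[:len(avail)]
            for df in (used, avail):
                ext = env.extract_covariates(
                    df.assign(timestamp=pd.Timestamp("2012-10-01",
                                                     tz="UTC")),
                    [cov_map[c] for c in SEAL_COVARIATES])
                for c in SEAL_COVARIATES:
                    df[c] = ext[cov_map[c]].to_numpy()
            table = rsf.build_table(used, avail, SEAL_COVARIATES,
                                    weight=cfg.weight)
            screen = rsf.screen_collinearity(table, SEAL_COVARIATES,
                                             r_max=0.61)
            model = rsf.fit_weighted_rsf(table, SEAL_COVARIATES,
                                         sigma0_sq=cfg.sigma0_sq)
            extra = {"dist_colony": env.layers[dist_layer].values}
            scores = rsf.predict_scores(model, env, extra_layers=extra)
            bm = fearscape.bin_scores(scores, domain=ud.mask,
                                      colony=cname)
            binned[period].append(bm)
            colony_results[cname]["models"][period] = model
            colony_results[cname]["screen"] = screen
            if cfg.run_cv and len(ids) >= 3:
                cv = validation.cv_rsf(
                    table, SEAL_COVARIATES, scheme="loo",
                    seed=seed, fit_kwargs={
                        "sigma0_sq": cfg.sigma0_sq, "maxfev": 25})
                colony_results[cname]["cv"][period] = cv
    fear_day = fearscape.overlay_max(binned["day"], period="day")
    fear_night = fearscape.overlay_max(binned["night"], period="night")
    return colony_results, fear_day, fear_night


def build_catch_layers(bundle):
    env = bundle["env"]
    fish = bundle["fisheries"]
    layers = {}
    for fleet, key in (("purse_seiner", "purse"), ("trawler", "trawl")):
        grid = catch_grid_spec(env.grid, fleet)
        cg = rasterize_catch(fish[fish["fleet"] == fleet], fleet, grid)
        layers[key] = resample_to_grid(cg.covariate, env.grid, name=key)
        env.layers[key] = layers[key]
    return layers


def gannet_foraging_rsf(bundle, per_fix, trip_df, fear_day, cfg: RunConfig,
                        seed: int):
    """Daytime foraging RSF against VAR(1) null-track availability."""
    env = bundle["env"]
    sim_cfg: SimConfig = bundle["cfg"]
    colony_xy = sim_cfg.gannet_colony_xy
    rng = np.random.default_rng(seed)
    sea = env.sea_mask
    grid = env.grid

    def sea_test(x, y):
        row, col = grid.index_of(x, y)
        if row < 0:
            return False
        return bool(sea[row, col])

    used = per_fix[(per_fix["state"] == "forage")
                   & per_fix["is_day"]].copy()
    avail_rows = []
    for track in bundle["gannet_tracks"]:
        track_i = trajectory.reinterpolate(track)
        sims = availability.simulate_var1_trips(
            track_i, n=cfg.n_sim_tracks, rng=rng, sea_test=sea_test)
        av = availability.available_foraging_locations(
            sims, seg_kwargs=dict(cfg.seg_kwargs, seed=seed),
            colony_xy=colony_xy, shore_distance=_shore_distance)
        av["individual_id"] = track.individual_id
        avail_rows.append(av)
    avail = pd.concat(avail_rows, ignore_index=True)

    def add_covs(df):
        df = df.copy()
        df["seal_index"] = fear_day.raster.sample(df["x"].to_numpy(),
                                                  df["y"].to_numpy())
        for key in ("purse", "trawl"):
            df[key] = env.layers[key].sample(df["x"].to_numpy(),
                                             df["y"].to_numpy())
        return df

    used = add_covs(used)
    avail = add_covs(avail)
    table = rsf.build_table(used, avail, GANNET_COVARIATES,
                            weight=cfg.weight)
    screen = rsf.screen_collinearity(table, GANNET_COVARIATES, r_max=0.62)
    models = {}
    tactic_of = trip_df.groupby("individual_id")["tactic"] \
        .agg(lambda s: s.dropna().mode().iat[0]
             if len(s.dropna()) else None)
    table = table.assign(
        tactic=table["individual_id"].map(tactic_of))
    models["all"] = rsf.fit_weighted_rsf(table, GANNET_COVARIATES,
                                         sigma0_sq=cfg.sigma0_sq)
    for tactic in ("rest_at_colony", "rest_at_sea"):
        sub = table[table["tactic"] == tactic]
        if sub["individual_id"].nunique() >= 2 \
                and (sub["case"] == 1).sum() >= 50:
            models[tactic] = rsf.fit_weighted_rsf(
                sub, GANNET_COVARIATES, sigma0_sq=cfg.sigma0_sq)
    cv = None
    if cfg.run_cv and table["individual_id"].nunique() >= 5:
        cv = validation.cv_rsf(table, GANNET_COVARIATES, scheme="kfold",
                               seed=seed,
                               fit_kwargs={"sigma0_sq": cfg.sigma0_sq,
                                           "maxfev": 25})
    return models, screen, cv, table


def diel_analysis(bundle, per_fix, trip_df, fear_day, fear_night,
                  cfg: RunConfig, seed: int):
    """Diel model + summary quantities for rest-at-sea birds."""
    env = bundle["env"]
    bird_tactic = summary.majority_tactic(trip_df)
    sea_birds = bird_tactic[bird_tactic == "rest_at_sea"].index

    day_forage = per_fix[(per_fix["individual_id"].isin(sea_birds))
                         & per_fix["is_day"]
                         & (per_fix["state"] == "forage")].copy()
    night_rest = per_fix[(per_fix["individual_id"].isin(sea_birds))
                         & ~per_fix["is_day"]
                         & (per_fix["state"] == "rest")].copy()

    def add_covs(df, fear):
        df = df.copy()
        df["seal_index"] = fear.raster.sample(df["x"].to_numpy(),
                                              df["y"].to_numpy())
        ext = env.extract_covariates(df, ["sst"])
        df["sst"] = ext["sst"].to_numpy()
        for key in ("purse", "trawl"):
            df[key] = env.layers[key].sample(df["x"].to_numpy(),
                                             df["y"].to_numpy())
        return df

    day_forage = add_covs(day_forage, fear_day)
    night_rest = add_covs(night_rest, fear_night)
    table = diel.build_diel_table(day_forage, night_rest)
    screen = rsf.screen_collinearity(table, diel.DIEL_COVARIATES,
                                     r_max=0.4)
    candidates = diel.fit_diel_candidates(table, seed=seed)
    best = candidates[0]
    curves = {c: diel.response_curve(best, c)
              for c in diel.DIEL_COVARIATES}
    return {"day_forage": day_forage, "night_rest": night_rest,
            "table": table, "screen": screen,
            "candidates": candidates, "best": best, "curves": curves,
            "bird_tactic": bird_tactic}


def summarize(bundle, per_fix, trip_df, diel_out, cfg: RunConfig):
    """Habitat-use table and derived diel quantities."""
    bird_tactic = diel_out["bird_tactic"]
    day_forage = diel_out["day_forage"].assign(
        group="day_forage_rest_at_sea", period="day_forage")
    night_rest = diel_out["night_rest"].assign(
        group="night_rest_rest_at_sea", period="night_rest")
    colony_birds = bird_tactic[bird_tactic == "rest_at_colony"].index
    col_day = per_fix[(per_fix["individual_id"].isin(colony_birds))
                      & per_fix["is_day"]
                      & (per_fix["state"] == "forage")].copy()
    col_day["group"] = "day_forage_rest_at_colony"
    col_day["period"] = "day_forage"
    for c in ("seal_index", "sst", "purse", "trawl"):
        if c not in col_day.columns:
            col_day[c] = np.nan

    variables = ["dist_shore", "dist_colony", "bathymetry", "seal_index",
                 "purse", "trawl", "sst"]
    loc_cols = ["individual_id", "year", "group", "period", "dist_shore",
                "dist_colony", "seal_index", "sst", "purse", "trawl"]
    env = bundle["env"]
    frames = []
    for df in (col_day, day_forage, night_rest):
        df = df.copy()
        ext = env.extract_covariates(df, ["bathymetry"])
        df["bathymetry"] = ext["bathymetry"].to_numpy()
        frames.append(df[loc_cols + ["bathymetry"]])
    locations = pd.concat(frames, ignore_index=True)
    habitat = summary.habitat_use_summary(locations, variables)

    shifts, shift_ci = summary.diel_shift(
        locations[locations["group"].isin(
            ["day_forage_rest_at_sea", "night_rest_rest_at_sea"])])
    tactics = summary.tactic_proportions(bird_tactic)
    mean_day_idx = float(day_forage["seal_index"].mean())
    mean_night_idx = float(night_rest["seal_index"].mean())
    risk_red = fearscape.percent_risk_reduction(mean_day_idx,
                                                mean_night_idx)
    try:
        dsst = summary.delta_sst(habitat)
    except KeyError:
        dsst = np.nan
    return {"habitat": habitat, "shifts": shifts, "shift_ci": shift_ci,
            "tactics": tactics, "risk_reduction_pct": risk_red,
            "mean_day_index": mean_day_idx,
            "mean_night_index": mean_night_idx,
            "delta_sst": dsst}


STAGE_ORDER = ["simulate", "segment", "rsf-seal", "fearscape",
               "rsf-gannet", "diel", "summarize"]


def run_pipeline(cfg: RunConfig, until: str = "summarize") -> dict:
    """Execute the stage chain on a (synthetic) cohort; return results.

    ``until`` stops after the named stage (one of ``STAGE_ORDER``), so
    each Methods-style stage is independently runnable.  When
    ``cfg.outdir`` is set, artifacts (CSV tables, ASCII rasters, JSON
    reports) are written there; the run is reproducible from ``cfg.seed``.
    """
    if until not in STAGE_ORDER:
        raise ValueError(f"unknown stage {until!r}")
    stop = STAGE_ORDER.index(until)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(5)]
    logger.info("stage: simulate")
    bundle = generate_all(cfg.sim_config(), seed=seeds[0],
                          outdir=cfg.outdir)
    build_catch_layers(bundle)
    if stop < 1:
        return {"bundle": bundle, "config": cfg}
    logger.info("stage: segmentation")
    per_fix, trip_df = segment_gannets(bundle, cfg, seed=seeds[1])
    if stop < 2:
        return {"bundle": bundle, "per_fix": per_fix, "trips": trip_df,
                "config": cfg}
    logger.info("stage: seal RSFs + fearscape")
    colony_results, fear_day, fear_night = fit_seal_models(
        bundle, cfg, seed=seeds[2])
    if stop < 4:
        return {"bundle": bundle, "per_fix": per_fix, "trips": trip_df,
                "seal": colony_results, "fear_day": fear_day,
                "fear_night": fear_night, "config": cfg}
    logger.info("stage: gannet foraging RSF")
    g_models, g_screen, g_cv, g_table = gannet_foraging_rsf(
        bundle, per_fix, trip_df, fear_day, cfg, seed=seeds[3])
    if stop < 5:
        return {"bundle": bundle, "per_fix": per_fix, "trips": trip_df,
                "seal": colony_results, "fear_day": fear_day,
                "fear_night": fear_night, "gannet_models": g_models,
                "gannet_cv": g_cv, "gannet_table": g_table, "config": cfg}
    logger.info("stage: diel model")
    diel_out = diel_analysis(bundle, per_fix, trip_df, fear_day,
                             fear_night, cfg, seed=seeds[4])
    if stop < 6:
        return {"bundle": bundle, "per_fix": per_fix, "trips": trip_df,
                "seal": colony_results, "fear_day": fear_day,
                "fear_night": fear_night, "gannet_models": g_models,
                "gannet_cv": g_cv, "gannet_table": g_table,
                "diel": diel_out, "config": cfg}
    logger.info("stage: summary")
    summ = summarize(bundle, per_fix, trip_df, diel_out, cfg)

    results = {
        "bundle": bundle, "per_fix": per_fix, "trips": trip_df,
        "seal": colony_results, "fear_day": fear_day,
        "fear_night": fear_night, "gannet_models": g_models,
        "gannet_cv": g_cv, "gannet_table": g_table,
        "diel": diel_out, "summary": summ, "config": cfg,
    }
    if cfg.outdir:
        _write_artifacts(results, Path(cfg.outdir))
    return results


def _write_artifacts(results, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    results["per_fix"].drop(columns=["timestamp"], errors="ignore") \
        .to_csv(outdir / "per_fix_states.csv", index=False)
    results["trips"].to_csv(outdir / "trip_tactics.csv", index=False)
    results["fear_day"].raster.write_ascii(outdir / "fearscape_day.asc")
    results["fear_night"].raster.write_ascii(
        outdir / "fearscape_night.asc")
    summ = results["summary"]
    summ["habitat"].table.to_csv(outdir / "habitat_summary.csv")
    report = {
        "config": {k: v for k, v in vars(results["config"]).items()},
        "tactics": summ["tactics"],
        "night_shift_km": {"mean": summ["shift_ci"][0],
                           "lo": summ["shift_ci"][1],
                           "hi": summ["shift_ci"][2]},
        "risk_reduction_pct": summ["risk_reduction_pct"],
        "delta_sst": summ["delta_sst"],
        "diel_best_forms": results["diel"]["best"].forms,
        "diel_best_aicc": results["diel"]["best"].aicc,
        "gannet_rsf": {k: m.report()
                       for k, m in results["gannet_models"].items()},
        "seal_cv_mean_rs": {
            c: {p: cv.mean_rs for p, cv in res["cv"].items()}
            for c, res in results["seal"].items()},
    }
    if results["gannet_cv"] is not None:
        report["gannet_cv_mean_rs"] = results["gannet_cv"].mean_rs
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
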