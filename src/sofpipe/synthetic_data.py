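"""Synthetic study system with known ground truth.

Generates every input the pipeline consumes: a coastal-shelf environment
(land west of x = 0, bathymetry deepening offshore, SST warming gently
offshore), Argos-like seal tracks from three colonies drawn from a known
habitat-selection intensity, GPS-like 1-min gannet foraging trips with
known behavioral states, a known rest-at-colony / rest-at-sea tactic mix
and a known nocturnal offshore shift, and fisheries catch records with
purse-seiners inshore and trawlers over the shelf break.  Every
ground-truth quantity is recorded in a manifest for parameter-recovery
tests.

Default parameters mirror the study system's scale (3 seal colonies, 25
seals, ~200 gannets); ``SimConfig.test_scale()`` is a smaller cohort with
the same generative structure for fast runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geo_env import (EnvStack, Grid, Raster, unproject_km_to_lonlat)
from .trajectory import Track, solar_elevation

GANNET_COLONY_LONLAT = (17.93, -33.05)   # reference point of the projection

# per-state kinematics: speed mean/sd (km/h) and per-minute heading noise
STATE_SPEED = {"rest": (1.0, 0.4), "forage": (9.0, 2.5),
               "commute": (38.0, 6.0)}
STATE_HEADING_SD = {"rest": 0.5, "forage": 1.2, "commute": 0.06}


@dataclass
class SimConfig:
    """All knobs of the synthetic study system, with recorded truth."""

    # grid (km, land at x < 0)
    x_min: float = -40.0
    x_max: float = 240.0
    y_min: float = -360.0
    y_max: float = 480.0
    resolution: float = 4.0
    # seal system
    n_seal_colonies: int = 3
    seal_colony_y: tuple = (400.0, 12.0, -230.0)
    seals_per_colony: tuple = (8, 12, 5)
    seal_fixes_per_seal: int = 500
    seal_range_km: float = 150.0
    seal_beta_true: dict = field(default_factory=lambda: {
        "dist_colony": -0.8, "bathymetry": 0.4, "slope": 0.0})
    seal_years: tuple = (2003, 2012, 2003)
    # gannet system
    n_gannets: int = 197
    trips_per_bird: tuple = (1, 3)
    tactic_mix_rest_at_sea: float = 0.72
    night_shift_km: float = 13.0
    night_shift_sd_km: float = 6.0
    forage_dist_shore_mean: float = 40.0
    forage_dist_shore_sd: float = 10.0
    forage_alongshore_sd: float = 60.0
    gannet_years: tuple = (2012, 2013, 2014)
    # environment
    shelf_slope_m_per_km: float = 8.0
    sst_base: float = 16.0
    sst_offshore_per_km: float = 0.3 / 13.0   # +0.3 C over the night shift
    # fisheries
    purse_records_per_year: int = 400
    trawl_records_per_year: int = 200
    purse_inshore_scale_km: float = 12.0
    trawl_center_km: float = 65.0
    trawl_sd_km: float = 12.0

    @classmethod
    def test_scale(cls) -> "SimConfig":
        """Small cohort with identical generative structure."""
        return cls(x_min=-20.0, x_max=140.0, y_min=-160.0, y_max=200.0,
                   seal_colony_y=(120.0, 10.0, -100.0),
                   seals_per_colony=(5, 5, 5),
                   seal_fixes_per_seal=300,
                   seal_range_km=90.0,
                   n_gannets=16, trips_per_bird=(1, 1),
                   forage_alongshore_sd=40.0,
                   purse_records_per_year=200,
                   trawl_records_per_year=120)

    @property
    def grid(self) -> Grid:
        nx = int(round((self.x_max - self.x_min) / self.resolution))
        ny = int(round((self.y_max - self.y_min) / self.resolution))
        return Grid(x0=self.x_min, y0=self.y_min, cell=self.resolution,
                    nx=nx, ny=ny)

    @property
    def gannet_colony_xy(self) -> tuple[float, float]:
        return (2.0, 0.0)

    @property
    def seal_colonies_xy(self) -> list[tuple[float, float]]:
        return [(2.0, y) for y in self.seal_colony_y[:self.n_seal_colonies]]


def generate_environment(cfg: SimConfig, seed: int = 0) -> EnvStack:
    """Deterministic (given seed) coastal-shelf environment stack."""
    rng = np.random.default_rng(seed)
    grid = cfg.grid
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers)

    rough = gaussian_filter(rng.standard_normal(xc.shape), sigma=3.0)
    rough /= max(np.abs(rough).max(), 1e-9)
    offshore = np.maximum(xc, 0.0)
    bathy = np.where(
        xc > 0.0,
        -(cfg.shelf_slope_m_per_km * offshore) * (1.0 + 0.25 * rough) - 5.0,
        20.0 + 30.0 * np.abs(rough))
    gy, gx = np.gradient(bathy, grid.cell * 1000.0)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    env = EnvStack(grid=grid, ref_lonlat=GANNET_COLONY_LONLAT)
    env.add_layer("bathymetry", bathy)
    env.add_layer("slope", slope)
    env.add_layer("dist_shore", np.maximum(xc, 0.0))
    cxy = cfg.gannet_colony_xy
    env.add_layer("dist_colony_gannet",
                  np.hypot(xc - cxy[0], yc - cxy[1]))
    for i, (sx, sy) in enumerate(cfg.seal_colonies_xy):
        env.add_layer(f"dist_colony_seal{i}",
                      np.hypot(xc - sx, yc - sy))
    sst_noise = gaussian_filter(rng.standard_normal(xc.shape), sigma=5.0)
    sst_noise /= max(np.abs(sst_noise).max(), 1e-9)
    for month in (9, 10, 11):
        sst = (cfg.sst_base + cfg.sst_offshore_per_km * offshore
               + 0.15 * (month - 10) + 0.2 * sst_noise)
        env.sst_monthly[month] = Raster(grid=grid, values=sst,
                                        name=f"sst_month{month:02d}")
    return env


def _standardize_domain(values: np.ndarray):
    mu = float(values.mean())
    sd = float(values.std())
    return (values - mu) / (sd if sd > 0 else 1.0), mu, sd


def generate_seal_tracks(cfg: SimConfig, env: EnvStack, seed: int = 0,
                         seals_per_colony=None, fixes_per_seal=None):
    """Argos-like seal fixes drawn from a known selection intensity.

    Within each colony's at-sea range, fix density is proportional to
    exp(beta' x) with beta on the range-standardized covariate scale;
    the manifest records both the standardized truth and its raw-scale
    equivalent per colony.
    """
    rng = np.random.default_rng(seed)
    grid = env.grid
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers)
    sea = env.sea_mask
    tracks, manifest_colonies = [], []
    spc = seals_per_colony or cfg.seals_per_colony
    nfix = fixes_per_seal or cfg.seal_fixes_per_seal
    covs = ["dist_colony", "bathymetry", "slope"]
    for ci, (sx, sy) in enumerate(cfg.seal_colonies_xy):
        dist_col = np.hypot(xc - sx, yc - sy)
        in_range = sea & (dist_col <= cfg.seal_range_km)
        layer_vals = {"dist_colony": dist_col,
                      "bathymetry": env.layers["bathymetry"].values,
                      "slope": env.layers["slope"].values}
        eta = np.zeros(in_range.sum())
        raw_beta = {}
        for name in covs:
            v = layer_vals[name][in_range]
            v_std, _, sd = _standardize_domain(v)
            b = cfg.seal_beta_true.get(name, 0.0)
            eta += b * v_std
            raw_beta[name] = b / sd
        w = np.exp(eta - eta.max())
        w /= w.sum()
        rows, cols = np.nonzero(in_range)
        year = cfg.seal_years[ci % len(cfg.seal_years)]
        t0 = pd.Timestamp(f"{year}-09-01T00:00:00Z")
        for s in range(spc[ci % len(spc)]):
            pick = rng.choice(len(rows), size=nfix, p=w)
            jit = rng.uniform(0, 1, size=(nfix, 2))
            px = grid.x0 + (cols[pick] + jit[:, 0]) * grid.cell
            py = grid.y0 + (grid.ny - 1 - rows[pick] + jit[:, 1]) * grid.cell
            gaps_h = rng.uniform(2.0, 6.0, size=nfix)
            times = t0 + pd.to_timedelta(np.cumsum(gaps_h), unit="h")
            df = pd.DataFrame({"timestamp": times, "x": px, "y": py})
            tracks.append(Track(
                individual_id=f"seal_c{ci}_{s}", fixes=df, species="seal",
                sensor="Argos", colony=GANNET_COLONY_LONLAT,
                colony_name=f"colony{ci}"))
        manifest_colonies.append({
            "colony": f"colony{ci}", "xy": [sx, sy], "year": year,
            "beta_std": dict(cfg.seal_beta_true),
            "beta_raw": raw_beta,
            "range_km": cfg.seal_range_km})
    manifest = {"colonies": manifest_colonies,
                "fixes_per_seal": nfix}
    return tracks, manifest


def seal_recovery_dataset(cfg: SimConfig, env: EnvStack, seed: int,
                          n_seals: int = 10, fixes_per_seal: int = 600,
                          ratio: int = 5, colony_index: int = 0):
    """Used/available table with exact availability for recovery tests.

    Available points are uniform over the colony's *generative* at-sea
    range (rather than an estimated UD), so the contrast is exactly
    well-specified and any estimation error is the estimator's own.
    Returns (used, available, manifest-entry) frames carrying the three
    seal covariates and individual ids.
    """
    rng = np.random.default_rng(seed)
    tracks, manifest = generate_seal_tracks(
        cfg, env, seed=seed,
        seals_per_colony=tuple(n_seals if i == colony_index else 0
                               for i in range(cfg.n_seal_colonies)),
        fixes_per_seal=fixes_per_seal)
    fixes = pd.concat([t.fixes.assign(individual_id=t.individual_id)
                       for t in tracks], ignore_index=True)
    grid = env.grid
    sx, sy = cfg.seal_colonies_xy[colony_index]
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers)
    in_range = env.sea_mask & (np.hypot(xc - sx, yc - sy)
                               <= cfg.seal_range_km)
    rows, cols = np.nonzero(in_range)
    pick = rng.integers(0, len(rows), size=ratio * len(fixes))
    jit = rng.uniform(0, 1, size=(len(pick), 2))
    ax = grid.x0 + (cols[pick] + jit[:, 0]) * grid.cell
    ay = grid.y0 + (grid.ny - 1 - rows[pick] + jit[:, 1]) * grid.cell
    used = fixes[["x", "y", "individual_id"]].copy()
    avail = pd.DataFrame({"x": ax, "y": ay})
    avail["individual_id"] = np.resize(
        used["individual_id"].unique(), len(avail))
    for df in (used, avail):
        r, c = grid.index_of(df["x"].to_numpy(), df["y"].to_numpy())
        df["bathymetry"] = env.layers["bathymetry"].values[r, c]
        df["slope"] = env.layers["slope"].values[r, c]
        df["dist_colony"] = np.hypot(df["x"] - sx, df["y"] - sy)
    return used, avail, manifest["colonies"][colony_index]


def _daylight_minutes(date: pd.Timestamp, lonlat) -> tuple[int, int]:
    """(dawn, dusk) minutes-of-day UTC at a site, by scanning elevation."""
    minutes = pd.date_range(date.normalize(), periods=1440, freq="min",
                            tz="UTC")
    elev = solar_elevation(minutes, np.full(1440, lonlat[0]),
                           np.full(1440, lonlat[1]))
    day = elev > 0
    idx = np.nonzero(day)[0]
    return int(idx[0]), int(idx[-1])


def _draw_forage_center(cfg: SimConfig, env: EnvStack, rng,
                        purse_field: np.ndarray | None):
    """Forage target: inshore-offset normal, nudged toward purse catch."""
    for _ in range(200):
        cand_x = rng.normal(cfg.forage_dist_shore_mean,
                            cfg.forage_dist_shore_sd, size=8)
        cand_y = rng.normal(0.0, cfg.forage_alongshore_sd, size=8)
        ok = (cand_x > 5.0) & env.grid.contains(cand_x, cand_y)
        if not ok.any():
            continue
        cand_x, cand_y = cand_x[ok], cand_y[ok]
        if purse_field is None:
            return float(cand_x[0]), float(cand_y[0])
        row, col = env.grid.index_of(cand_x, cand_y)
        inten = purse_field[row, col]
        p = np.exp(inten - inten.max())
        p /= p.sum()
        k = rng.choice(len(cand_x), p=p)
        return float(cand_x[k]), float(cand_y[k])
    return cfg.forage_dist_shore_mean, 0.0


def _simulate_trip(cfg: SimConfig, env: EnvStack, rng, bird: str,
                   trip_id: str, year: int, tactic: str,
                   purse_field: np.ndarray | None):
    """One 1-min-resolution central-place trip with known states."""
    colony = np.array(cfg.gannet_colony_xy)
    day0 = pd.Timestamp(f"{year}-10-{int(rng.integers(1, 28)):02d}T00:00Z")
    dawn, dusk = _daylight_minutes(day0, GANNET_COLONY_LONLAT)
    start_min = dawn + int(rng.integers(20, 90))
    t = day0 + pd.Timedelta(minutes=start_min)

    pos = colony.copy()
    heading = rng.uniform(-math.pi / 3, math.pi / 3)  # roughly offshore
    target = np.array(_draw_forage_center(cfg, env, rng, purse_field))
    phase = "commute_out"
    bout_end = None
    rest_target = None
    day_forage_x: list[float] = []
    records = []
    minute = start_min
    x_hi = cfg.x_max - 2 * cfg.resolution
    y_lo, y_hi = cfg.y_min + 2 * cfg.resolution, cfg.y_max - 2 * cfg.resolution

    for _step in range(60 * 48):
        state = ("rest" if phase.startswith("rest")
                 else ("forage" if phase == "forage" else "commute"))
        mu, sd = STATE_SPEED[state]
        speed = max(rng.normal(mu, sd), 0.05)     # km/h
        if phase == "rest_colony":
            pos = colony + rng.normal(0.0, 0.05, size=2)
            speed = abs(rng.normal(0.2, 0.1))
        else:
            if phase in ("commute_out", "commute_offshore",
                         "commute_home"):
                vec = target - pos
                heading = math.atan2(vec[1], vec[0]) \
                    + rng.normal(0.0, STATE_HEADING_SD["commute"])
            else:
                heading += rng.normal(0.0, STATE_HEADING_SD[state])
            step_km = speed / 60.0
            pos = pos + step_km * np.array([math.cos(heading),
                                            math.sin(heading)])
            if pos[0] < 0.5:
                pos[0] = 1.0 - pos[0] if pos[0] > -0.5 else 0.5
            pos[0] = min(pos[0], x_hi)
            pos[1] = min(max(pos[1], y_lo), y_hi)
        minute += 1
        t = t + pd.Timedelta(minutes=1)
        records.append((t, pos[0], pos[1], state, speed))
        if state == "forage":
            day_forage_x.append(pos[0])

        minute_of_day = minute % 1440
        after_dusk = (minute >= dusk) if minute < 1440 else \
            (minute_of_day >= dusk or minute_of_day < dawn)
        next_dawn = dawn + 1440
        past_next_dawn = minute >= next_dawn

        if phase == "commute_out" and np.linalg.norm(target - pos) < 2.0:
            phase = "forage"
            bout_end = minute + int(rng.normal(60, 15))
        elif phase == "forage":
            if tactic == "rest_at_colony":
                # leave in time to reach the colony before dark
                travel_min = np.linalg.norm(colony - pos) / 38.0 * 60.0
                near_dusk = minute >= dusk - travel_min - 60
            else:
                near_dusk = minute >= dusk - 75
            if near_dusk:
                if tactic == "rest_at_colony":
                    phase, target = "commute_home", colony
                else:
                    # per-night variability is wide: day and night
                    # distance-to-shore distributions overlap broadly even
                    # though the mean shift is cfg.night_shift_km
                    # offset from the day's mean foraging distance to
                    # shore, so the generative diel shift is exactly the
                    # configured mean
                    shift = cfg.night_shift_km \
                        + rng.normal(0.0, cfg.night_shift_sd_km)
                    base_x = (float(np.mean(day_forage_x))
                              if day_forage_x else pos[0])
                    rest_target = np.array([
                        max(min(base_x + shift, x_hi), 3.0),
                        pos[1] + rng.normal(0.0, 8.0)])
                    phase, target = "commute_offshore", rest_target
            elif bout_end is not None and minute >= bout_end:
                hop = pos + rng.normal(0.0, 12.0, size=2)
                hop[0] = max(hop[0], 6.0)
                target = hop
                phase = "commute_out"
        elif phase == "commute_home" \
                and np.linalg.norm(target - pos) < 0.8:
            phase = "rest_colony"   # roost overnight, depart after dawn
        elif phase == "commute_offshore" \
                and np.linalg.norm(target - pos) < 1.5:
            phase = "rest_sea"
        elif phase in ("rest_colony", "rest_sea"):
            if (past_next_dawn and minute_of_day >= dawn + 15) \
                    or (phase == "rest_colony" and past_next_dawn):
                if phase == "rest_colony":
                    break    # trip ends at the colony after sunrise
                phase, target = "commute_home", colony

    df = pd.DataFrame(records,
                      columns=["timestamp", "x", "y", "state", "speed"])
    track = Track(individual_id=bird,
                  fixes=df[["timestamp", "x", "y"]],
                  species="gannet", sensor="GPS",
                  colony=GANNET_COLONY_LONLAT, trip_id=trip_id)
    truth = df[["timestamp", "state", "speed"]].copy()
    truth["individual_id"] = bird
    truth["trip_id"] = trip_id
    truth["year"] = year
    return track, truth


def generate_gannet_trips(cfg: SimConfig, env: EnvStack, seed: int = 0,
                          purse_field: np.ndarray | None = None):
    """All gannet trips plus per-fix state truth and per-trip tactic truth.

    Returns (tracks, fix_truth, trip_truth, manifest).  Tactics are drawn
    per bird from the configured mix and apply to all of a bird's trips.
    """
    rng = np.random.default_rng(seed)
    tracks, truths, trip_rows = [], [], []
    for b in range(cfg.n_gannets):
        bird = f"gannet_{b:03d}"
        tactic = ("rest_at_sea"
                  if rng.random() < cfg.tactic_mix_rest_at_sea
                  else "rest_at_colony")
        year = int(rng.choice(cfg.gannet_years))
        lo, hi = cfg.trips_per_bird
        n_trips = int(rng.integers(lo, hi + 1))
        for k in range(n_trips):
            trip_id = f"{bird}_t{k}"
            track, truth = _simulate_trip(cfg, env, rng, bird, trip_id,
                                          year, tactic, purse_field)
            tracks.append(track)
            truths.append(truth)
            trip_rows.append({"trip_id": trip_id, "individual_id": bird,
                              "year": year, "tactic": tactic})
    fix_truth = pd.concat(truths, ignore_index=True)
    trip_truth = pd.DataFrame(trip_rows)
    manifest = {
        "tactic_mix_rest_at_sea": cfg.tactic_mix_rest_at_sea,
        "night_shift_km": cfg.night_shift_km,
        "state_speed_kmh": STATE_SPEED,
        "n_gannets": cfg.n_gannets,
        "n_rest_at_sea_true": int(
            (trip_truth.groupby("individual_id")["tactic"].first()
             == "rest_at_sea").sum()),
    }
    return tracks, fix_truth, trip_truth, manifest


def generate_fisheries(cfg: SimConfig, env: EnvStack, seed: int = 0
                       ) -> pd.DataFrame:
    """Catch records: purse-seiners inshore, trawlers over the shelf break."""
    rng = np.random.default_rng(seed)
    years = cfg.gannet_years
    rows = []
    y_span = (cfg.y_min + 10.0, cfg.y_max - 10.0)
    for year in years:
        for _ in range(cfg.purse_records_per_year):
            x = 2.0 + rng.exponential(cfg.purse_inshore_scale_km)
            x = min(x, cfg.x_max - 5.0)
            y = rng.uniform(*y_span)
            rows.append((x, y, int(year), "purse_seiner",
                         float(rng.lognormal(2.5, 1.0))))
        for _ in range(cfg.trawl_records_per_year):
            x = max(rng.normal(cfg.trawl_center_km, cfg.trawl_sd_km), 5.0)
            x = min(x, cfg.x_max - 5.0)
            y = rng.uniform(*y_span)
            rows.append((x, y, int(year), "trawler",
                         float(rng.lognormal(2.8, 0.9))))
    df = pd.DataFrame(rows, columns=["x", "y", "year", "fleet", "tonnes"])
    lon, lat = unproject_km_to_lonlat(df["x"], df["y"],
                                      GANNET_COLONY_LONLAT)
    df["lon"], df["lat"] = lon, lat
    return df


def write_tracks_csv(tracks: list[Track], path) -> None:
    frames = []
    for tr in tracks:
        df = tr.fixes[["timestamp", "lon", "lat"]].copy()
        df.insert(0, "id", tr.trip_id or tr.individual_id)
        df["sensor"] = tr.sensor
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def generate_all(cfg: SimConfig, seed: int = 0, outdir=None) -> dict:
    """Generate the full synthetic data set; optionally write artifacts.

    Seeds for the sub-generators are derived deterministically from
    ``seed``.  Returns a bundle with env, tracks, truths and the manifest.
    """
    ss = np.random.SeedSequence(seed)
    s_env, s_seal, s_gannet, s_fish = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(4)]
    env = generate_environment(cfg, seed=s_env)
    fisheries = generate_fisheries(cfg, env, seed=s_fish)

    # purse intensity field (log scale) used to bias forage-site choice
    from .geo_env import catch_grid_spec, rasterize_catch, resample_to_grid
    purse = rasterize_catch(fisheries[fisheries["fleet"] == "purse_seiner"],
                            "purse_seiner",
                            catch_grid_spec(env.grid, "purse_seiner"))
    purse_field = resample_to_grid(purse.covariate, env.grid).values

    seal_tracks, seal_manifest = generate_seal_tracks(cfg, env, seed=s_seal)
    gannet_tracks, fix_truth, trip_truth, gannet_manifest = \
        generate_gannet_trips(cfg, env, seed=s_gannet,
                              purse_field=purse_field)
    manifest = {
        "seed": seed,
        "config": asdict(cfg),
        "seals": seal_manifest,
        "gannets": gannet_manifest,
        "sst_offshore_per_km": cfg.sst_offshore_per_km,
    }
    bundle = {"cfg": cfg, "env": env, "fisheries": fisheries,
              "seal_tracks": seal_tracks, "gannet_tracks": gannet_tracks,
              "fix_truth": fix_truth, "trip_truth": trip_truth,
              "manifest": manifest}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        env.write(outdir / "env")
        fisheries.to_csv(outdir / "fisheries.csv", index=False)
        write_tracks_csv(seal_tracks, outdir / "seal_tracks.csv")
        write_tracks_csv(gannet_tracks, outdir / "gannet_tracks.csv")
        fix_truth.to_csv(outdir / "gannet_fix_truth.csv", index=False)
        trip_truth.to_csv(outdir / "gannet_trip_truth.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return bundle
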