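"""Track ingestion, reinterpolation, and kinematic descriptors.

A :class:`Track` is an ordered series of fixes for one individual.  From a
1-min reinterpolated track we derive the two descriptors used to classify
behavior: speed smoothed over the two steps before and after each focal fix,
and the turning angle measured at constant step length (the angle at the
focal fix between the backward and forward crossings of a circle whose
radius is the track's median step length).  Day/night is assigned from solar
elevation at each fix's position and time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo_env import project_lonlat_to_km, unproject_km_to_lonlat

TRACK_CSV_COLUMNS = ["id", "timestamp", "lon", "lat", "sensor"]


@dataclass
class Track:
    """Ordered geolocations of one individual.

    ``fixes`` holds columns ``timestamp`` (UTC), ``lon``, ``lat`` and the
    projected ``x``/``y`` (km about the colony).  Timestamps must be
    strictly increasing and there must be at least two fixes.
    """

    individual_id: str
    fixes: pd.DataFrame
    species: str = "gannet"
    sensor: str = "GPS"
    colony: tuple[float, float] = (0.0, 0.0)  # lon, lat
    colony_name: str = ""
    trip_id: str = ""

    def __post_init__(self):
        df = self.fixes.reset_index(drop=True).copy()
        if len(df) < 2:
            raise ValueError("a track needs at least 2 fixes")
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
        t = df["timestamp"].dt.tz_localize(None).to_numpy()
        if not (np.diff(t.astype(np.int64)) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if "x" not in df.columns or "y" not in df.columns:
            x, y = project_lonlat_to_km(df["lon"], df["lat"], self.colony)
            df["x"], df["y"] = x, y
        if "lon" not in df.columns:
            lon, lat = unproject_km_to_lonlat(df["x"], df["y"], self.colony)
            df["lon"], df["lat"] = lon, lat
        if not np.isfinite(df[["lon", "lat", "x", "y"]].to_numpy()).all():
            raise ValueError("non-finite coordinates in track")
        self.fixes = df

    def __len__(self):
        return len(self.fixes)

    @property
    def xy(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(float)

    @property
    def seconds(self) -> np.ndarray:
        t = self.fixes["timestamp"].dt.tz_localize(None).to_numpy()
        return (t - t[0]).astype("timedelta64[ns]").astype(np.int64) / 1e9


def read_tracks_csv(path, colony=(0.0, 0.0), species="gannet") -> list[Track]:
    """Read tracks from CSV (columns id, timestamp, lon, lat[, sensor])."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    tracks = []
    for tid, sub in df.groupby("id", sort=False):
        sensor = str(sub["sensor"].iloc[0]) if "sensor" in sub else "GPS"
        tracks.append(Track(individual_id=str(tid),
                            fixes=sub[["timestamp", "lon", "lat"]],
                            species=species, sensor=sensor, colony=colony))
    return tracks


def reinterpolate(track: Track, interval: float = 60.0,
                  max_gap: float = 600.0) -> Track:
    """Linear reinterpolation to a regular time step (default 1 min).

    Output fixes sit at exact ``interval`` multiples from the first fix,
    interpolated linearly in projected km space.  Gaps longer than
    ``max_gap`` seconds split the track into bursts (column ``burst``);
    positions are never interpolated across a gap.
    """
    sec = track.seconds
    if sec[-1] < interval:
        raise ValueError("track shorter than one interpolation interval")
    xy = track.xy
    gaps = np.diff(sec)
    burst_of_fix = np.concatenate([[0], np.cumsum(gaps > max_gap)])

    out_t, out_xy, out_burst = [], [], []
    for b in np.unique(burst_of_fix):
        sel = burst_of_fix == b
        s, exy = sec[sel], xy[sel]
        if s[-1] - s[0] < interval:
            continue
        t0 = math.ceil(s[0] / interval) * interval
        tq = np.arange(t0, s[-1] + 1e-9, interval)
        out_t.append(tq)
        out_xy.append(np.column_stack([np.interp(tq, s, exy[:, 0]),
                                       np.interp(tq, s, exy[:, 1])]))
        out_burst.append(np.full(len(tq), b, dtype=int))
    if not out_t:
        raise ValueError("no burst long enough to reinterpolate")
    tq = np.concatenate(out_t)
    xyq = np.vstack(out_xy)
    t_abs = (track.fixes["timestamp"].iloc[0]
             + pd.to_timedelta(tq, unit="s"))
    df = pd.DataFrame({"timestamp": t_abs, "x": xyq[:, 0], "y": xyq[:, 1],
                       "burst": np.concatenate(out_burst)})
    lon, lat = unproject_km_to_lonlat(df["x"], df["y"], track.colony)
    df["lon"], df["lat"] = lon, lat
    return replace(track, fixes=df)


def step_lengths(track: Track) -> np.ndarray:
    """Per-step great-plane distances (km); length len(track)-1."""
    return np.hypot(*np.diff(track.xy, axis=0).T)


def smoothed_speed(track: Track, halfwidth: int = 2) -> np.ndarray:
    """Speed at each fix, smoothed over two steps before and after (km/h).

    The value at fix *i* is the mean of the step speeds connecting fixes
    ``i-halfwidth .. i+halfwidth`` — the ``halfwidth`` steps entering and
    the ``halfwidth`` steps leaving the focal fix (four steps in the
    interior for the default).  The window is symmetric about the fix, so
    the descriptor is invariant under time reversal; windows are
    truncated at the track ends.
    """
    sec = track.seconds
    dt_h = np.diff(sec) / 3600.0
    sp = step_lengths(track) / dt_h  # speed of step j (fix j -> j+1)
    n = len(track)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - halfwidth)
        hi = min(len(sp), i + halfwidth)
        out[i] = sp[lo:hi].mean() if hi > lo else sp[min(i, len(sp) - 1)]
    return out


def turn_angle_csl(track: Track, convention: str = "last_inside",
                   radius: float | None = None) -> np.ndarray:
    """Turning angle at constant step length, in [0, pi]; NaN near ends.

    For focal fix *i* and circle radius *r* (the track's median step length
    unless ``radius`` is given): the backward anchor is the first fix,
    scanning backward from *i*, at distance >= r from the focal; the
    forward anchor depends on ``convention``:

    - ``"last_inside"`` (default): the last consecutive fix after the focal
      still inside the circle (the fix just before the forward crossing);
      when the very first forward fix already lies at distance >= r, that
      crossing fix is used.
    - ``"first_outside"``: the first forward fix at distance >= r.

    The returned angle is pi minus the vertex angle at the focal, so that
    straight-line travel gives 0 and an exact reversal gives pi.
    """
    xy = track.xy
    n = len(xy)
    r = float(np.median(step_lengths(track))) if radius is None else radius
    if r <= 0:
        raise ValueError("median step length must be positive")
    out = np.full(n, np.nan)
    for i in range(n):
        p = xy[i]
        back = None
        for j in range(i - 1, -1, -1):
            if np.hypot(*(xy[j] - p)) >= r:
                back = xy[j]
                break
        if back is None:
            continue
        fwd = None
        if convention == "first_outside":
            for j in range(i + 1, n):
                if np.hypot(*(xy[j] - p)) >= r:
                    fwd = xy[j]
                    break
        elif convention == "last_inside":
            last_in = None
            for j in range(i + 1, n):
                if np.hypot(*(xy[j] - p)) < r:
                    last_in = xy[j]
                else:
                    fwd = xy[j] if last_in is None else last_in
                    break
            # never crossed: no defined forward anchor
        else:
            raise ValueError(f"unknown convention {convention!r}")
        if fwd is None:
            continue
        u, v = back - p, fwd - p
        nu, nv = np.hypot(*u), np.hypot(*v)
        if nu == 0 or nv == 0:
            continue
        c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
        theta = math.acos(c)  # vertex angle at the focal
        out[i] = math.pi - theta
    return out


# ---------------------------------------------------------------------------
# Solar position (NOAA algorithm) and day/night annotation
# ---------------------------------------------------------------------------

def solar_elevation(timestamps, lon, lat) -> np.ndarray:
    """Solar elevation angle (degrees) from the NOAA solar-position formulas.

    Vectorized over fixes; no atmospheric refraction (the day/night cut at
    0 degrees is insensitive to it at the one-minute scale used here).
    """
    t = pd.DatetimeIndex(pd.to_datetime(timestamps, utc=True)) \
        .tz_convert("UTC").tz_localize(None)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    # Julian day from Unix epoch
    jd = t.to_numpy().astype("datetime64[s]").astype(np.int64) / 86400.0 \
        + 2440587.5
    jc = (jd - 2451545.0) / 36525.0  # Julian century

    geom_mean_long = np.mod(280.46646 + jc * (36000.76983 + jc * 3.032e-4),
                            360.0)
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 1.537e-4 * jc)
    ecc = 0.016708634 - jc * (4.2037e-5 + 1.267e-7 * jc)
    ma = np.radians(geom_mean_anom)
    eq_ctr = (np.sin(ma) * (1.914602 - jc * (0.004817 + 1.4e-5 * jc))
              + np.sin(2 * ma) * (0.019993 - 1.01e-4 * jc)
              + np.sin(3 * ma) * 2.89e-4)
    true_long = geom_mean_long + eq_ctr
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.radians(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc *
                 (5.9e-4 - jc * 1.813e-3))) / 60.0) / 60.0
    obliq_corr = mean_obliq + 0.00256 * np.cos(np.radians(omega))
    oc = np.radians(obliq_corr)
    decl = np.arcsin(np.sin(oc) * np.sin(np.radians(app_long)))

    var_y = np.tan(oc / 2.0) ** 2
    ml = np.radians(geom_mean_long)
    eq_time = 4.0 * np.degrees(
        var_y * np.sin(2 * ml)
        - 2.0 * ecc * np.sin(ma)
        + 4.0 * ecc * var_y * np.sin(ma) * np.cos(2 * ml)
        - 0.5 * var_y ** 2 * np.sin(4 * ml)
        - 1.25 * ecc ** 2 * np.sin(2 * ma))  # minutes

    minutes_utc = (t.hour * 60 + t.minute + t.second / 60.0
                   + t.microsecond / 6e7)
    true_solar_min = np.mod(minutes_utc + eq_time + 4.0 * lon, 1440.0)
    hour_angle = true_solar_min / 4.0 - 180.0
    ha = np.radians(hour_angle)
    lat_r = np.radians(lat)
    cos_zenith = (np.sin(lat_r) * np.sin(decl)
                  + np.cos(lat_r) * np.cos(decl) * np.cos(ha))
    zenith = np.degrees(np.arccos(np.clip(cos_zenith, -1.0, 1.0)))
    return 90.0 - zenith


def annotate_daynight(track: Track, threshold_deg: float = 0.0) -> np.ndarray:
    """True where the sun is above ``threshold_deg`` (default: horizon)."""
    elev = solar_elevation(track.fixes["timestamp"],
                           track.fixes["lon"], track.fixes["lat"])
    return elev > threshold_deg


def derive_step_series(track: Track, colony_xy=(0.0, 0.0),
                       shore_distance=None,
                       angle_convention: str = "last_inside") -> pd.DataFrame:
    """All per-fix kinematic/context descriptors for a reinterpolated track.

    ``shore_distance`` is a callable (x, y) -> km; when None the column is
    omitted.  Returns the fixes frame with appended columns step_length,
    smoothed_speed, turn_angle, is_day, dist_colony[, dist_shore].
    """
    df = track.fixes.copy()
    sl = step_lengths(track)
    df["step_length"] = np.append(sl, np.nan)
    df["smoothed_speed"] = smoothed_speed(track)
    df["turn_angle"] = turn_angle_csl(track, convention=angle_convention)
    df["is_day"] = annotate_daynight(track)
    cx, cy = colony_xy
    df["dist_colony"] = np.hypot(df["x"] - cx, df["y"] - cy)
    if shore_distance is not None:
        df["dist_shore"] = shore_distance(df["x"].to_numpy(),
                                          df["y"].to_numpy())
    return df
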