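"""Availability designs for the two RSF stages.

Seals: available points are drawn uniformly (5 per used point) inside the
sea-clipped 95% kernel utilization distribution (UD) of each colony-year's
fixes.  Gannets: availability comes from null tracks simulated with a
first-order vector autoregression (VAR(1)) fitted to each observed trip's
step increments — tracks with the trip's duration, start point and speed
structure but no habitat preference — which are then segmented exactly
like real tracks, the daytime foraging fixes becoming the available set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from . import segmentation, trajectory
from .geo_env import Grid, Raster
from .trajectory import Track


@dataclass
class UDRegion:
    """95% kernel utilization distribution on a raster grid.

    ``mask`` is True on pixels inside the isopleth (sea-clipped when a
    land mask is supplied); ``density`` is the KDE evaluated on the grid.
    """

    grid: Grid
    mask: np.ndarray
    density: np.ndarray
    isopleth: float = 0.95
    colony: str = ""
    year: int | None = None

    @property
    def area_km2(self) -> float:
        return float(self.mask.sum()) * self.grid.cell ** 2

    def contains(self, x, y) -> np.ndarray:
        row, col = self.grid.index_of(x, y)
        out = np.zeros(np.shape(row), dtype=bool)
        ok = np.asarray(row) >= 0
        out[ok] = self.mask[row[ok], col[ok]]
        return out

    def boundary_polygons(self):
        """Isopleth boundary as shapely polygons (via marching squares)."""
        from shapely.geometry import Polygon
        from skimage import measure
        polys = []
        padded = np.pad(self.mask.astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            rr = contour[:, 0] - 1.0
            cc = contour[:, 1] - 1.0
            xs = self.grid.x0 + (cc + 0.5) * self.grid.cell
            ys = self.grid.y0 + (self.grid.ny - 1 - rr + 0.5) * self.grid.cell
            if len(xs) >= 4:
                polys.append(Polygon(np.column_stack([xs, ys])))
        return polys


def kernel_ud(points: np.ndarray, grid: Grid,
              bandwidth: float | str = "silverman",
              isopleth: float = 0.95,
              sea_mask: np.ndarray | None = None,
              colony: str = "", year: int | None = None) -> UDRegion:
    """Bivariate Gaussian kernel UD and its smallest-area isopleth.

    The isopleth is the smallest-area set of pixels containing
    ``isopleth`` of the total kernel density mass; land pixels are removed
    afterwards when ``sea_mask`` is given.  Degenerate (collinear) point
    sets are rejected.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 30:
        raise ValueError("kernel_ud needs at least 30 points")
    if np.linalg.matrix_rank(np.cov(pts.T)) < 2:
        raise ValueError("degenerate (collinear) points")
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers)
    dens = kde(np.vstack([xc.ravel(), yc.ravel()])).reshape(grid.ny, grid.nx)
    order = np.argsort(dens.ravel())[::-1]
    csum = np.cumsum(dens.ravel()[order])
    csum /= csum[-1]
    k = int(np.searchsorted(csum, isopleth)) + 1
    mask = np.zeros(dens.size, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(dens.shape)
    if sea_mask is not None:
        mask &= sea_mask
        if not mask.any():
            raise ValueError("UD isopleth entirely on land")
    return UDRegion(grid=grid, mask=mask, density=dens, isopleth=isopleth,
                    colony=colony, year=year)


def sample_available_random(ud: UDRegion, n_used: int, ratio: int = 5,
                            rng=None) -> np.ndarray:
    """Uniform random points inside the UD isopleth (ratio per used point).

    Points are uniform over the isopleth's pixels with within-pixel
    jitter; reproducible given ``rng``.
    """
    if not ud.mask.any():
        raise ValueError("empty UD region")
    rng = np.random.default_rng(rng)
    n = int(ratio) * int(n_used)
    rows, cols = np.nonzero(ud.mask)
    pick = rng.integers(0, len(rows), size=n)
    jitter = rng.uniform(0.0, 1.0, size=(n, 2))
    x = ud.grid.x0 + (cols[pick] + jitter[:, 0]) * ud.grid.cell
    y = ud.grid.y0 + (ud.grid.ny - 1 - rows[pick] + jitter[:, 1]) \
        * ud.grid.cell
    return np.column_stack([x, y])


@dataclass
class VAR1Fit:
    """First-order vector autoregression on step increments (dx, dy)."""

    intercept: np.ndarray       # (2,)
    phi: np.ndarray             # (2, 2)
    chol_sigma: np.ndarray      # Cholesky factor of innovation covariance
    fallback_crw: bool = False


def fit_var1(track: Track) -> VAR1Fit:
    """Least-squares VAR(1) fit to a trip's step-increment series."""
    inc = np.diff(track.xy, axis=0)
    if len(inc) < 5:
        raise ValueError("too few increments for VAR(1)")
    Y = inc[1:]
    X = np.column_stack([np.ones(len(inc) - 1), inc[:-1]])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    sigma = resid.T @ resid / max(len(Y) - 3, 1)
    try:
        chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(2))
        fallback = False
    except np.linalg.LinAlgError:
        # degenerate covariance: correlated-random-walk fallback with
        # matched marginal step variances
        chol = np.diag(np.sqrt(np.maximum(np.diag(sigma), 0.0)))
        fallback = True
    return VAR1Fit(intercept=coef[0], phi=coef[1:].T, chol_sigma=chol,
                   fallback_crw=fallback)


def simulate_var1_trips(trip: Track, n: int = 10, rng=None,
                        sea_test=None, max_retries: int = 100
                        ) -> list[Track]:
    """Simulate habitat-blind null tracks with the trip's structure.

    Each simulation starts at the observed trip's start (the colony),
    keeps its fix count and timestamps, and draws increments from the
    fitted VAR(1).  When ``sea_test(x, y)`` is given, innovations that
    land a fix ashore are redrawn up to ``max_retries`` times, then the
    increment is reflected — trip length is preserved exactly.
    """
    if len(trip) < 20:
        raise ValueError("trip too short to fit VAR(1)")
    rng = np.random.default_rng(rng)
    fit = fit_var1(trip)
    inc_obs = np.diff(trip.xy, axis=0)
    n_steps = len(inc_obs)
    start = trip.xy[0]
    sims = []
    for s in range(n):
        pos = np.empty((n_steps + 1, 2))
        pos[0] = start
        prev = inc_obs[0]
        for t in range(n_steps):
            ok = False
            for _try in range(max_retries):
                eps = fit.chol_sigma @ rng.standard_normal(2)
                step = fit.intercept + fit.phi @ prev + eps
                cand = pos[t] + step
                if sea_test is None or sea_test(cand[0], cand[1]):
                    ok = True
                    break
            if not ok:
                step = -step  # reflect: retrace rather than run aground
                cand = pos[t] + step
            pos[t + 1] = cand
            prev = step
        df = pd.DataFrame({"timestamp": trip.fixes["timestamp"].to_numpy(),
                           "x": pos[:, 0], "y": pos[:, 1]})
        sim = Track(individual_id=trip.individual_id,
                    fixes=df, species=trip.species, sensor=trip.sensor,
                    colony=trip.colony,
                    trip_id=f"{trip.trip_id or trip.individual_id}_sim{s}")
        sims.append(sim)
    return sims


def available_foraging_locations(sim_tracks: list[Track],
                                 seg_kwargs: dict | None = None,
                                 colony_xy=(0.0, 0.0),
                                 shore_distance=None) -> pd.DataFrame:
    """Daytime foraging fixes of null tracks = the available sample.

    Runs the trajectory descriptors and segmentation-clustering on every
    simulated track and returns its daytime fixes labeled ``forage``.
    Tracks whose segmentation is degenerate (e.g. never leaving the
    commute regime) are flagged in ``attrs['n_degenerate']``.
    """
    seg_kwargs = dict(seg_kwargs or {})
    rows = []
    n_degen = 0
    for sim in sim_tracks:
        series = trajectory.derive_step_series(
            sim, colony_xy=colony_xy, shore_distance=shore_distance)
        beh = segmentation.segment_cluster(series, **seg_kwargs)
        if beh.degenerate:
            n_degen += 1
        sel = (series["is_day"].to_numpy()
               & (beh.states == "forage"))
        sub = series.loc[sel, ["timestamp", "x", "y"]].copy()
        sub["individual_id"] = sim.individual_id
        sub["trip_id"] = sim.trip_id
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=["timestamp", "x", "y", "individual_id",
                              "trip_id"])
    out.attrs["n_degenerate"] = n_degen
    return out
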