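"""Day/night seascape-of-fear rasters from colony-specific RSF maps.

Each colony's predicted seal-occurrence scores are split into ten
equal-count bins (1 = lowest occurrence, 10 = highest) over that colony's
own masked extent; the regional fearscape takes, pixel by pixel, the
maximum bin among the colony maps, separately for day and night.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geo_env import Grid, Raster

logger = logging.getLogger(__name__)


@dataclass
class BinnedMap:
    raster: Raster                 # integer bins 1..n_bins, NaN off-domain
    edges: np.ndarray
    n_bins: int
    degenerate: bool = False
    colony: str = ""


@dataclass
class FearscapeRaster:
    """Seal-occurrence index in {1..10} per sea pixel, one per diel period."""

    raster: Raster
    period: str                    # 'day' | 'night'
    provenance: dict = field(default_factory=dict)
    source_colony: np.ndarray | None = None   # which map supplied the max

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


def bin_scores(scores: Raster, n_bins: int = 10,
               domain: np.ndarray | None = None,
               method: str = "quantile", colony: str = "") -> BinnedMap:
    """Quantile (equal-count) binning of RSF scores into 1..n_bins.

    ``domain`` restricts binning to a pixel mask (e.g. the colony UD);
    elsewhere the output is NaN.  With fewer distinct values than bins the
    result is flagged degenerate (a constant raster maps wholly to bin 1).
    ``method='equal'`` gives equal-interval bins instead.
    """
    vals = scores.values
    dom = np.isfinite(vals) if domain is None else \
        (domain & np.isfinite(vals))
    v = vals[dom]
    if v.size == 0:
        raise ValueError("no pixels to bin")
    degenerate = np.unique(v).size < n_bins
    if method == "quantile":
        edges = np.quantile(v, np.linspace(0, 1, n_bins + 1))
    elif method == "equal":
        edges = np.linspace(v.min(), v.max(), n_bins + 1)
    else:
        raise ValueError(f"unknown binning method {method!r}")
    inner = edges[1:-1]
    binned = np.full(vals.shape, np.nan)
    # right-closed inner edges keep ties in the lower bin, preserving
    # monotonicity: a higher score never gets a lower bin
    binned[dom] = np.searchsorted(inner, v, side="left") + 1
    if degenerate:
        logger.warning("bin_scores: fewer than %d distinct score values",
                       n_bins)
    return BinnedMap(raster=Raster(grid=scores.grid, values=binned,
                                   name="binned_scores"),
                     edges=edges, n_bins=n_bins, degenerate=degenerate,
                     colony=colony)


def overlay_max(binned_maps: list[BinnedMap], period: str) -> FearscapeRaster:
    """Pixel-wise maximum bin across colony maps (ties -> lowest index)."""
    if not binned_maps:
        raise ValueError("no maps to overlay")
    grid = binned_maps[0].raster.grid
    for m in binned_maps[1:]:
        if m.raster.grid != grid:
            raise ValueError("overlay_max: grid mismatch between maps")
    stack = np.stack([m.raster.values for m in binned_maps])
    filled = np.where(np.isfinite(stack), stack, -np.inf)
    out = filled.max(axis=0)
    src = filled.argmax(axis=0)      # first (lowest colony index) on ties
    none = ~np.isfinite(stack).any(axis=0)
    out[none] = np.nan
    src = np.where(none, -1, src)
    prov = {"colonies": [m.colony for m in binned_maps],
            "edges": {m.colony: m.edges.tolist() for m in binned_maps}}
    return FearscapeRaster(
        raster=Raster(grid=grid, values=out, name=f"fearscape_{period}"),
        period=period, provenance=prov, source_colony=src)


def extract_fear_index(fear_day: FearscapeRaster,
                       fear_night: FearscapeRaster,
                       x, y, is_day) -> np.ndarray:
    """Per-point seal-occurrence index, period-matched.

    Day points read the daytime fearscape, night points the nighttime one;
    points on land or outside either raster yield NaN (counted in the
    log).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    is_day = np.asarray(is_day, dtype=bool)
    out = np.full(len(x), np.nan)
    out[is_day] = fear_day.raster.sample(x[is_day], y[is_day])
    out[~is_day] = fear_night.raster.sample(x[~is_day], y[~is_day])
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        logger.info("extract_fear_index: %d of %d points missing",
                    n_missing, len(out))
    return out


def percent_risk_reduction(mean_day_index: float,
                           mean_night_index: float) -> float:
    """Percent drop in mean encounter index from day foraging to night rest.

    100 * (day - night) / day; e.g. day 6.4 and night 4.8 give 25%.
    """
    if not mean_day_index > 0:
        raise ValueError("mean day index must be positive")
    return 100.0 * (mean_day_index - mean_night_index) / mean_day_index
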