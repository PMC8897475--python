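"""Environmental raster stack, local projection, and fisheries-grid tools.

All spatial work happens on a single master grid in a local equirectangular
projection (km east/north of a reference point, normally the gannet colony).
The study region spans well under ten degrees, so the distance distortion of
the local projection is negligible at these scales.

Rasters are read and written as ESRI ASCII grids (plain-text ``.asc``), the
interchange format used throughout the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
NM_TO_KM = 1.852

# fleets and their log-book grid resolutions (nautical miles)
FLEET_RESOLUTION_NM = {"purse_seiner": 10.0, "trawler": 20.0}


def project_lonlat_to_km(lon, lat, ref):
    """Project lon/lat (degrees) to local km about ``ref`` (a lon/lat pair).

    Azimuthal equidistant about the reference point: distances from the
    reference are exact and pairwise distances within a 500-km disc are
    correct to well under 1%.  Latitudes poleward of 89 degrees are
    rejected (the study region is temperate and the azimuth becomes
    ill-conditioned at the poles).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    ref_lon, ref_lat = float(ref[0]), float(ref[1])
    if np.any(np.abs(lat) >= 89.0) or abs(ref_lat) >= 89.0:
        raise ValueError("polar latitudes (|lat| >= 89) are not supported")
    phi0 = math.radians(ref_lat)
    phi = np.radians(lat)
    dlam = np.radians(lon - ref_lon)
    cos_c = (math.sin(phi0) * np.sin(phi)
             + math.cos(phi0) * np.cos(phi) * np.cos(dlam))
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    sin_c = np.sin(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(sin_c > 1e-12, c / np.where(sin_c > 1e-12, sin_c, 1.0),
                     1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
    y = EARTH_RADIUS_KM * k * (math.cos(phi0) * np.sin(phi)
                               - math.sin(phi0) * np.cos(phi)
                               * np.cos(dlam))
    if np.ndim(lon) == 0 and np.ndim(lat) == 0:
        return float(x), float(y)
    return x, y


def unproject_km_to_lonlat(x, y, ref):
    """Inverse of :func:`project_lonlat_to_km`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ref_lon, ref_lat = float(ref[0]), float(ref[1])
    phi0 = math.radians(ref_lat)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_KM
    small = rho < 1e-9
    rho_safe = np.where(small, 1.0, rho)
    phi = np.arcsin(np.clip(
        np.cos(c) * math.sin(phi0)
        + y * np.sin(c) * math.cos(phi0) / rho_safe, -1.0, 1.0))
    lam = math.radians(ref_lon) + np.arctan2(
        x * np.sin(c),
        rho_safe * math.cos(phi0) * np.cos(c)
        - y * math.sin(phi0) * np.sin(c))
    lat = np.where(small, ref_lat, np.degrees(phi))
    lon = np.where(small, ref_lon, np.degrees(lam))
    if np.ndim(x) == 0 and np.ndim(y) == 0:
        return float(lon), float(lat)
    return lon, lat


@dataclass(frozen=True)
class Grid:
    """Regular raster grid in projected km coordinates.

    ``x0``/``y0`` are the coordinates of the *lower-left corner* of the
    lower-left cell; rows of the value array run north-to-south (row 0 is
    the northernmost), matching the ESRI ASCII layout.
    """

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        # north-to-south to match array rows
        return self.y0 + (np.arange(self.ny)[::-1] + 0.5) * self.cell

    @property
    def extent(self):
        return (self.x0, self.x0 + self.nx * self.cell,
                self.y0, self.y0 + self.ny * self.cell)

    def index_of(self, x, y):
        """Row/col of the cell containing each point (nearest-cell lookup).

        Points outside the extent get index -1 in both row and col.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row_s = np.floor((y - self.y0) / self.cell).astype(int)  # from south
        row = self.ny - 1 - row_s
        bad = (col < 0) | (col >= self.nx) | (row < 0) | (row >= self.ny)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def contains(self, x, y):
        row, _ = self.index_of(x, y)
        return np.asarray(row) >= 0


@dataclass
class Raster:
    """A single co-registered layer: 2-D values on a :class:`Grid`."""

    grid: Grid
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"raster {self.name!r}: shape {self.values.shape} does not "
                f"match grid ({self.grid.ny}, {self.grid.nx})")

    def sample(self, x, y):
        """Nearest-cell values at points; NaN outside the extent."""
        row, col = self.grid.index_of(x, y)
        out = np.full(np.shape(row), np.nan)
        ok = np.asarray(row) >= 0
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def write_ascii(self, path):
        write_ascii_grid(path, self.grid, self.values)

    @classmethod
    def read_ascii(cls, path, name=""):
        grid, values = read_ascii_grid(path)
        return cls(grid=grid, values=values, name=name or Path(path).stem)


def write_ascii_grid(path, grid: Grid, values: np.ndarray,
                     nodata: float = -9999.0) -> None:
    vals = np.where(np.isfinite(values), values, nodata)
    header = (f"ncols {grid.nx}\nnrows {grid.ny}\n"
              f"xllcorner {grid.x0!r}\nyllcorner {grid.y0!r}\n"
              f"cellsize {grid.cell!r}\nNODATA_value {nodata!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path):
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh)
    grid = Grid(x0=header["xllcorner"], y0=header["yllcorner"],
                cell=header["cellsize"], nx=int(header["ncols"]),
                ny=int(header["nrows"]))
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return grid, values


@dataclass
class EnvStack:
    """Named set of co-registered environmental layers on one master grid.

    Static layers (bathymetry in m, slope in degrees, dist_shore and
    dist_colony_* in km, fisheries catch covariates as log(tonnes+1)) live
    in ``layers``; monthly sea-surface temperature lives in ``sst_monthly``
    keyed by calendar month.  ``land_mask`` is True exactly where bathymetry
    is above sea level.
    """

    grid: Grid
    layers: dict[str, Raster] = field(default_factory=dict)
    sst_monthly: dict[int, Raster] = field(default_factory=dict)
    ref_lonlat: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        for name, r in self.layers.items():
            if r.grid != self.grid:
                raise ValueError(f"layer {name!r} not on the master grid")

    @property
    def land_mask(self) -> np.ndarray:
        bathy = self.layers["bathymetry"].values
        return bathy > 0

    @property
    def sea_mask(self) -> np.ndarray:
        return ~self.land_mask

    def add_layer(self, name: str, values: np.ndarray) -> None:
        self.layers[name] = Raster(grid=self.grid, values=values, name=name)

    def sst_for_month(self, month: int) -> Raster:
        if not self.sst_monthly:
            raise KeyError("no SST layers in stack")
        if month in self.sst_monthly:
            return self.sst_monthly[month]
        # single climatology raster stored under key 0
        return self.sst_monthly[0]

    def extract_covariates(self, points: pd.DataFrame,
                           covariates: Iterable[str]) -> pd.DataFrame:
        """Nearest-cell covariate rows for projected points.

        ``points`` needs columns ``x``/``y`` (km) and, when ``sst`` is
        requested, a ``timestamp`` column whose calendar month selects the
        SST layer.  Points on land or outside the extent yield NaN rows and
        ``missing=True`` rather than silent zeros.
        """
        x = points["x"].to_numpy(float)
        y = points["y"].to_numpy(float)
        row, col = self.grid.index_of(x, y)
        inside = row >= 0
        on_land = np.zeros(len(points), dtype=bool)
        on_land[inside] = self.land_mask[row[inside], col[inside]]
        out = {}
        for name in covariates:
            if name == "sst":
                vals = np.full(len(points), np.nan)
                months = pd.DatetimeIndex(points["timestamp"]).month
                for m in np.unique(months):
                    sel = (months == m) & inside
                    if sel.any():
                        vals[sel] = self.sst_for_month(int(m)).values[
                            row[sel], col[sel]]
                out[name] = vals
            else:
                vals = np.full(len(points), np.nan)
                vals[inside] = self.layers[name].values[row[inside],
                                                        col[inside]]
                out[name] = vals
        df = pd.DataFrame(out, index=points.index)
        df["missing"] = (~inside) | on_land | df.isna().any(axis=1)
        df.loc[df["missing"], list(covariates)] = np.nan
        n_miss = int(df["missing"].sum())
        if n_miss:
            logger.info("extract_covariates: %d of %d points missing "
                        "(land/outside/no-data)", n_miss, len(df))
        return df

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, r in self.layers.items():
            r.write_ascii(directory / f"{name}.asc")
        for month, r in self.sst_monthly.items():
            r.write_ascii(directory / f"sst_month{month:02d}.asc")

    @classmethod
    def read(cls, directory, ref_lonlat=(0.0, 0.0)) -> "EnvStack":
        directory = Path(directory)
        layers, sst = {}, {}
        grid = None
        for path in sorted(directory.glob("*.asc")):
            r = Raster.read_ascii(path)
            grid = grid or r.grid
            if path.stem.startswith("sst_month"):
                sst[int(path.stem[-2:])] = r
            else:
                layers[path.stem] = r
        if grid is None:
            raise FileNotFoundError(f"no .asc rasters in {directory}")
        return cls(grid=grid, layers=layers, sst_monthly=sst,
                   ref_lonlat=ref_lonlat)


@dataclass
class CatchGrid:
    """Annual fisheries catch (tonnes per cell) on a fleet's log-book grid."""

    raster: Raster
    fleet: str
    year: int | None = None
    n_outside: int = 0

    @property
    def covariate(self) -> Raster:
        """log(tonnes + 1) layer used as an RSF covariate."""
        return Raster(grid=self.raster.grid,
                      values=np.log1p(self.raster.values),
                      name=f"log_{self.fleet}_catch")


def catch_grid_spec(extent_grid: Grid, fleet: str) -> Grid:
    """Fleet log-book grid covering ``extent_grid`` at the fleet's native
    nautical-mile resolution (purse-seiners 10x10 nmi, trawlers 20x20 nmi)."""
    cell = FLEET_RESOLUTION_NM[fleet] * NM_TO_KM
    x0, x1, y0, y1 = extent_grid.extent
    nx = max(1, int(math.ceil((x1 - x0) / cell)))
    ny = max(1, int(math.ceil((y1 - y0) / cell)))
    return Grid(x0=x0, y0=y0, cell=cell, nx=nx, ny=ny)


def rasterize_catch(records: pd.DataFrame, fleet: str,
                    grid: Grid) -> CatchGrid:
    """Sum catch records (columns x, y in km, tonnes) into grid cells.

    Records outside the grid extent are counted and logged, never silently
    dropped.  Negative tonnages are rejected.
    """
    vals = np.zeros((grid.ny, grid.nx))
    if len(records):
        t = records["tonnes"].to_numpy(float)
        if np.any(t < 0):
            raise ValueError("negative catch tonnage")
        row, col = grid.index_of(records["x"].to_numpy(float),
                                 records["y"].to_numpy(float))
        inside = row >= 0
        np.add.at(vals, (row[inside], col[inside]), t[inside])
        n_outside = int((~inside).sum())
    else:
        n_outside = 0
    if n_outside:
        logger.warning("rasterize_catch(%s): %d records outside extent",
                       fleet, n_outside)
    year = None
    if "year" in records.columns and len(records):
        years = records["year"].unique()
        year = int(years[0]) if len(years) == 1 else None
    raster = Raster(grid=grid, values=vals, name=f"{fleet}_catch")
    return CatchGrid(raster=raster, fleet=fleet, year=year,
                     n_outside=n_outside)


def resample_to_grid(src: Raster, grid: Grid, name: str = "") -> Raster:
    """Nearest-neighbour resampling of ``src`` onto the master grid."""
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers)
    vals = src.sample(xc.ravel(), yc.ravel()).reshape(grid.ny, grid.nx)
    return Raster(grid=grid, values=vals, name=name or src.name)
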