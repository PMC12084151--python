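"""Planar analysis grid and raster/NetCDF I/O helpers.

All rasters in this package live on a regular planar grid with square cells,
coordinates in kilometres from the domain's south-west corner; row 0 is the
southernmost row. Latitude enters only through a nominal domain-centre
latitude used for phenology rules and to convert northward offsets to
degrees (111.32 km per degree).

Raster files are written as plain single- or multi-band TIFF with the grid
geometry in a JSON sidecar (``<name>.tif`` + ``<name>.tif.json``); gridded
time series go to NetCDF3 via xarray's scipy backend.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

KM_PER_DEGREE_LAT = 111.32


@dataclass(frozen=True)
class Grid:
    """Regular planar grid; ``res_km`` cell size, row 0 = southernmost."""

    nx: int
    ny: int
    res_km: float
    center_lat: float = 31.0

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.res_km <= 0:
            raise ValueError("grid resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def extent_km(self) -> tuple[float, float]:
        return (self.nx * self.res_km, self.ny * self.res_km)

    @property
    def cell_area_m2(self) -> float:
        return (self.res_km * 1000.0) ** 2

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.res_km

    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.res_km

    def latitudes(self) -> np.ndarray:
        """Per-row latitude (degrees N), nominal centre at mid-domain."""
        y = self.y_centers()
        return self.center_lat + (y - y.mean()) / KM_PER_DEGREE_LAT

    def distance_from(self, x_km: float, y_km: float) -> np.ndarray:
        """(ny, nx) array of cell-centre distances from a point, km."""
        xx, yy = np.meshgrid(self.x_centers(), self.y_centers())
        return np.hypot(xx - x_km, yy - y_km)


def refine(grid: Grid, factor: int) -> Grid:
    return Grid(grid.nx * factor, grid.ny * factor, grid.res_km / factor,
                grid.center_lat)


def block_mean(fine: np.ndarray, factor: int) -> np.ndarray:
    """Aggregate a fine raster to a coarse one by block averaging."""
    ny, nx = fine.shape
    if ny % factor or nx % factor:
        raise ValueError("fine shape not an integer multiple of factor")
    return fine.reshape(ny // factor, factor, nx // factor, factor).mean(axis=(1, 3))


def block_sum(fine: np.ndarray, factor: int) -> np.ndarray:
    """Mass-conserving aggregation (e.g. population counts)."""
    ny, nx = fine.shape
    if ny % factor or nx % factor:
        raise ValueError("fine shape not an integer multiple of factor")
    return fine.reshape(ny // factor, factor, nx // factor, factor).sum(axis=(1, 3))


# ---------------------------------------------------------------------------
# I/O

def write_raster(path: str | Path, data: np.ndarray, grid: Grid,
                 band_names: list[str] | None = None, **attrs) -> Path:
    """Write a (ny, nx) or (bands, ny, nx) raster as TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(data))
    meta = {"grid": asdict(grid), "band_names": band_names, **attrs}
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, Grid, dict]:
    path = Path(path)
    data = tifffile.imread(path)
    with open(f"{path}.json") as fh:
        meta = json.load(fh)
    grid = Grid(**meta.pop("grid"))
    return data, grid, meta


def hourly_dataset(fields: dict[str, np.ndarray], grid: Grid,
                   start: str = "2019-05-28", **attrs) -> xr.Dataset:
    """Wrap (time, ny, nx) arrays in a CF-style xarray Dataset."""
    n_time = next(iter(fields.values())).shape[0]
    time = np.datetime64(start, "h") + np.arange(n_time)
    ds = xr.Dataset(
        {k: (("time", "y", "x"), np.asarray(v, dtype=np.float32))
         for k, v in fields.items()},
        coords={"time": time, "y": grid.y_centers(), "x": grid.x_centers()},
        attrs={"grid_convention": "row 0 = southernmost, cell centres, km",
               "res_km": grid.res_km, "center_lat": grid.center_lat, **attrs},
    )
    return ds


def write_netcdf(ds: xr.Dataset, path: str | Path) -> Path:
    path = Path(path)
    ds.to_netcdf(path, engine="scipy")
    return path


def grid_from_dataset(ds: xr.Dataset) -> Grid:
    return Grid(nx=ds.sizes["x"], ny=ds.sizes["y"],
                res_km=float(ds.attrs["res_km"]),
                center_lat=float(ds.attrs.get("center_lat", 31.0)))
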