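"""Gridded fields, regions, spatial statistics and NetCDF/CSV round trips.

Conventions
-----------
* Regular lat/lon grids with cell-centre registration.
* Fields are ``(time, lat, lon)`` float arrays; NaN marks missing data and
  every statistic is computed over the available cells only.
* Longitudes are normalised to [-180, 180); the supported domains never
  cross the antimeridian.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .calendars import eight_day_step

_LAT_NAMES = ("lat", "latitude", "nav_lat", "y")
_LON_NAMES = ("lon", "longitude", "nav_lon", "x")
_TIME_NAMES = ("time", "t", "date")

_AXIS_TOL = 1e-6  # degrees: allowed deviation from regular spacing


def _regular_axis(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError(f"{name} axis must be a non-empty 1-D vector")
    if values.size > 1:
        steps = np.diff(values)
        if not (np.all(steps > 0) or np.all(steps < 0)):
            raise ValueError(f"{name} axis must be strictly monotone")
        if np.ptp(np.abs(steps)) > _AXIS_TOL:
            raise ValueError(f"{name} axis is not regularly spaced (tol {_AXIS_TOL} deg)")
    return values


@dataclass(frozen=True)
class GeoGrid:
    """Regular lat/lon grid (cell centres)."""

    lats: np.ndarray
    lons: np.ndarray

    def __post_init__(self):
        lats = _regular_axis(self.lats, "latitude")
        lons = np.asarray(self.lons, dtype=float)
        # normalise to [-180, 180); supported domains never wrap
        lons = np.where(lons >= 180.0, lons - 360.0, lons)
        lons = _regular_axis(lons, "longitude")
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "lons", lons)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lats.size, self.lons.size

    @property
    def dlat(self) -> float:
        return float(np.abs(np.diff(self.lats)).mean()) if self.lats.size > 1 else np.nan

    @property
    def dlon(self) -> float:
        return float(np.abs(np.diff(self.lons)).mean()) if self.lons.size > 1 else np.nan

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeoGrid)
            and np.array_equal(self.lats, other.lats)
            and np.array_equal(self.lons, other.lons)
        )


@dataclass(frozen=True)
class Region:
    """Rectangular lat/lon box; bounds are inclusive of cell centres."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self):
        if not self.lat_min < self.lat_max:
            raise ValueError("lat_min must be < lat_max")
        if not self.lon_min < self.lon_max:
            raise ValueError("lon_min must be < lon_max")

    def contains(self, lat, lon):
        lat = np.asarray(lat)
        lon = np.asarray(lon)
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )


@dataclass
class GeoField:
    """A gridded variable on a (time, lat, lon) cube; NaN = missing."""

    grid: GeoGrid
    times: pd.DatetimeIndex
    values: np.ndarray
    units: str = ""
    name: str = "field"

    def __post_init__(self):
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.times),) + self.grid.shape
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(time, lat, lon) = {expected}"
            )

    @property
    def mask(self) -> np.ndarray:
        """True where data are missing."""
        return np.isnan(self.values)

    def copy_with(self, **changes) -> "GeoField":
        kwargs = dict(
            grid=self.grid, times=self.times, values=self.values.copy(),
            units=self.units, name=self.name,
        )
        kwargs.update(changes)
        return GeoField(**kwargs)

    def to_xarray(self) -> xr.DataArray:
        da = xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={"time": self.times, "lat": self.grid.lats, "lon": self.grid.lons},
            name=self.name or "field",
        )
        da.attrs["units"] = self.units
        da.lat.attrs["units"] = "degrees_north"
        da.lon.attrs["units"] = "degrees_east"
        return da

    @classmethod
    def from_xarray(cls, da: xr.DataArray) -> "GeoField":
        dims = {d.lower(): d for d in da.dims}
        tdim = next((dims[n] for n in _TIME_NAMES if n in dims), None)
        ydim = next((dims[n] for n in _LAT_NAMES if n in dims), None)
        xdim = next((dims[n] for n in _LON_NAMES if n in dims), None)
        if tdim is None or ydim is None or xdim is None:
            raise ValueError(
                f"variable {da.name!r} needs (time, lat, lon) axes; found dims {da.dims}"
            )
        da = da.transpose(tdim, ydim, xdim)
        grid = GeoGrid(np.asarray(da[ydim].values), np.asarray(da[xdim].values))
        times = pd.DatetimeIndex(da[tdim].values)
        return cls(
            grid=grid,
            times=times,
            values=np.asarray(da.values, dtype=float),
            units=str(da.attrs.get("units", "")),
            name=str(da.name or "field"),
        )


def read_field(path, var: str) -> GeoField:
    """Read one (time, lat, lon) variable from a CF-style NetCDF file.

    Axis order on disk is arbitrary; fill values are decoded to NaN.
    """
    with xr.open_dataset(path) as ds:
        if var not in ds.data_vars:
            available = ", ".join(sorted(ds.data_vars))
            raise KeyError(f"variable {var!r} not in file; available: {available}")
        return GeoField.from_xarray(ds[var].load())


def write_field(geofield: GeoField, path, var: str | None = None) -> None:
    """Write a field as classic NetCDF (CF-style axes, NaN encoded as fill)."""
    name = var or geofield.name or "field"
    da = geofield.to_xarray().rename(name)
    ds = da.to_dataset()
    ds.to_netcdf(
        path,
        format="NETCDF3_64BIT",
        engine="scipy",
        encoding={name: {"_FillValue": np.float64(-9.999e33)}},
    )


def subset(geofield: GeoField, region: Region) -> GeoField:
    """Cells whose centres fall inside ``region`` (bounds inclusive)."""
    lat_in = (geofield.grid.lats >= region.lat_min) & (geofield.grid.lats <= region.lat_max)
    lon_in = (geofield.grid.lons >= region.lon_min) & (geofield.grid.lons <= region.lon_max)
    if not lat_in.any() or not lon_in.any():
        raise ValueError("region does not intersect the grid")
    out = GeoField(
        grid=GeoGrid(geofield.grid.lats[lat_in], geofield.grid.lons[lon_in]),
        times=geofield.times,
        values=geofield.values[:, lat_in][:, :, lon_in],
        units=geofield.units,
        name=geofield.name,
    )
    if np.isnan(out.values).all():
        warnings.warn("subset region contains no valid data", stacklevel=2)
    return out


def region_mean(geofield: GeoField, region: Region, weighting: str = "cos-lat") -> pd.Series:
    """Area-mean time series over a region.

    ``weighting='cos-lat'`` (default) weights cells by the cosine of their
    latitude, the physically correct area weight on a regular grid;
    ``'none'`` averages cells equally. Time steps with no valid cell are NaN.
    """
    sub = subset(geofield, region)
    if weighting == "cos-lat":
        w = np.cos(np.deg2rad(sub.grid.lats))[:, None] * np.ones(sub.grid.shape[1])
    elif weighting == "none":
        w = np.ones(sub.grid.shape)
    else:
        raise ValueError("weighting must be 'cos-lat' or 'none'")
    valid = ~np.isnan(sub.values)
    wsum = np.where(valid, w, 0.0).sum(axis=(1, 2))
    vsum = np.where(valid, np.nan_to_num(sub.values) * w, 0.0).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(wsum > 0, vsum / wsum, np.nan)
    return pd.Series(means, index=sub.times, name=sub.name)


def valid_pixel_fraction(geofield: GeoField, region: Region) -> pd.Series:
    """Per-time fraction of unmasked cells inside ``region`` (0..1)."""
    sub = subset(geofield, region)
    n_cells = sub.grid.shape[0] * sub.grid.shape[1]
    frac = (~np.isnan(sub.values)).sum(axis=(1, 2)) / n_cells
    return pd.Series(frac, index=sub.times, name="valid_fraction")


_TARGET_STEP = {"daily": pd.Timedelta(days=1), "monthly": pd.Timedelta(days=28), "8day": pd.Timedelta(days=8)}


def _bin_labels(times: pd.DatetimeIndex, target: str) -> pd.DatetimeIndex:
    if target == "daily":
        return times.normalize()
    if target == "monthly":
        return pd.DatetimeIndex([pd.Timestamp(t.year, t.month, 1) for t in times])
    if target == "8day":
        steps = eight_day_step(times)
        return pd.DatetimeIndex(
            [pd.Timestamp(t.year, 1, 1) + pd.Timedelta(days=8 * int(s)) for t, s in zip(times, steps)]
        )
    raise ValueError("target must be 'daily', 'monthly' or '8day'")


def resample_time(obj, target: str):
    """Average a finer-resolution series or field into target bins.

    Bin means are taken over the available (unmasked) samples; bins with no
    valid sample are missing. The source must be strictly finer than the
    target resolution.
    """
    times = obj.index if isinstance(obj, pd.Series) else obj.times
    if target not in _TARGET_STEP:
        raise ValueError("target must be 'daily', 'monthly' or '8day'")
    if len(times) > 1:
        src_step = pd.Series(times).diff().median()
        if src_step >= _TARGET_STEP[target]:
            raise ValueError(
                f"source resolution ({src_step}) is not finer than target {target!r}"
            )
    labels = _bin_labels(times, target)
    codes, uniques = pd.factorize(labels, sort=True)
    if isinstance(obj, pd.Series):
        out = obj.groupby(codes).mean()  # skips NaN; empty bin -> absent
        out = out.reindex(range(len(uniques)))
        out.index = uniques
        return out.rename(obj.name)
    # GeoField: nan-mean per bin along the time axis
    nt = len(uniques)
    shape = (nt,) + obj.grid.shape
    sums = np.zeros(shape)
    counts = np.zeros(shape)
    valid = ~np.isnan(obj.values)
    np.add.at(sums, codes, np.where(valid, np.nan_to_num(obj.values), 0.0))
    np.add.at(counts, codes, valid.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return GeoField(grid=obj.grid, times=uniques, values=means, units=obj.units, name=obj.name)
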