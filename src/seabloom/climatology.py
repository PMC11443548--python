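"""Climatologies, anomalies, trends, smoothing and deposition aggregation.

A climatology is a per-period-of-year mean and standard deviation computed
over an explicit reference period (per-dataset: different satellite and
reanalysis records start in different years). Anomalies come in two
flavours: relative (% above the climatological mean) and standardized
(departure in climatological-SD units). Decadal trends are per-pixel OLS
slopes with the conventional two-sided t-test and a significance mask at
p >= 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calendars import period_codes
from .grids import GeoField

DEFAULT_MIN_SAMPLES = 5


@dataclass
class Climatology:
    """Per-period mean/SD over a reference period.

    ``mean``/``sd``/``count`` are indexed by ``codes`` along axis 0; for a
    gridded climatology the trailing axes are (lat, lon). SD uses ddof=1;
    periods with fewer than ``min_samples`` reference samples are flagged
    and yield missing anomalies.
    """

    period_kind: str
    codes: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray
    reference_period: tuple[pd.Timestamp, pd.Timestamp]
    min_samples: int = DEFAULT_MIN_SAMPLES

    @property
    def flagged(self) -> np.ndarray:
        return self.count < self.min_samples


def _obj_times_values(obj):
    if isinstance(obj, pd.Series):
        return pd.DatetimeIndex(obj.index), obj.to_numpy(dtype=float)
    if isinstance(obj, GeoField):
        return obj.times, obj.values
    raise TypeError(f"expected pandas Series or GeoField, got {type(obj).__name__}")


def build_climatology(
    obj,
    period_kind: str,
    reference_period: tuple,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> Climatology:
    """Per-period mean and SD over reference-period samples only."""
    times, values = _obj_times_values(obj)
    start, end = (pd.Timestamp(reference_period[0]), pd.Timestamp(reference_period[1]))
    in_ref = (times >= start) & (times <= end)
    if not in_ref.any():
        raise ValueError(
            f"reference period {start.date()}..{end.date()} lies outside the data span "
            f"{times.min().date()}..{times.max().date()}"
        )
    ref_times = times[in_ref]
    if ref_times.max() - ref_times.min() < pd.Timedelta(days=365):
        raise ValueError("reference period must span at least two years of data")
    codes = period_codes(ref_times, period_kind)
    vals = values[in_ref]

    uniq = np.unique(codes)
    trailing = vals.shape[1:]
    mean = np.full((uniq.size,) + trailing, np.nan)
    sd = np.full((uniq.size,) + trailing, np.nan)
    count = np.zeros((uniq.size,) + trailing)
    import warnings as _warnings

    for k, code in enumerate(uniq):
        sample = vals[codes == code]
        n = (~np.isnan(sample)).sum(axis=0)
        count[k] = n
        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean[k] = np.where(n > 0, np.nanmean(sample, axis=0), np.nan)
            sd[k] = np.where(n > 1, np.nanstd(sample, axis=0, ddof=1), np.nan)
    return Climatology(
        period_kind=period_kind, codes=uniq, mean=mean, sd=sd, count=count,
        reference_period=(start, end), min_samples=min_samples,
    )


def _period_lookup(clim: Climatology, times: pd.DatetimeIndex):
    """Broadcast the climatology onto a time axis: (mean, sd, flagged)."""
    codes = period_codes(times, clim.period_kind)
    pos = np.searchsorted(clim.codes, codes)
    pos_clipped = np.clip(pos, 0, clim.codes.size - 1)
    known = clim.codes[pos_clipped] == codes
    trailing = clim.mean.shape[1:]
    nan_row = np.full(trailing, np.nan) if trailing else np.nan
    mean = np.where(
        _expand(known, trailing), clim.mean[pos_clipped], nan_row
    )
    sd = np.where(_expand(known, trailing), clim.sd[pos_clipped], nan_row)
    flagged = clim.flagged[pos_clipped] | ~_expand(known, trailing)
    return mean, sd, flagged


def _expand(mask_1d: np.ndarray, trailing: tuple) -> np.ndarray:
    return mask_1d.reshape(mask_1d.shape + (1,) * len(trailing))


def _wrap_like(obj, values, units=None):
    if isinstance(obj, pd.Series):
        return pd.Series(values, index=obj.index, name=obj.name)
    out = obj.copy_with(values=values)
    if units is not None:
        out.units = units
    return out


def relative_anomaly(obj, clim: Climatology):
    """Percent above the climatological mean: 100 (x - m)/m.

    Missing where the climatological mean is non-positive or the period is
    undersampled (never an infinity).
    """
    times, values = _obj_times_values(obj)
    mean, _sd, flagged = _period_lookup(clim, times)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * (values - mean) / mean
    out = np.where((mean > 0) & ~flagged, out, np.nan)
    return _wrap_like(obj, out, units="%")


def standardized_anomaly(obj, clim: Climatology):
    """Departure from climatology in SD units: (x - m)/s."""
    times, values = _obj_times_values(obj)
    mean, sd, flagged = _period_lookup(clim, times)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (values - mean) / sd
    out = np.where((sd > 0) & ~flagged, out, np.nan)
    return _wrap_like(obj, out, units="SD")


def fill_gaps_linear(series: pd.Series) -> pd.Series:
    """Gap-free copy of a series: interior gaps linearly interpolated,
    leading/trailing gaps filled with the nearest valid value.

    Idempotent; requires at least two valid samples.
    """
    n_valid = series.notna().sum()
    if n_valid == 0:
        raise ValueError("cannot fill an all-missing series")
    if n_valid < 2:
        raise ValueError("need at least two valid samples to interpolate")
    return series.interpolate(method="linear").ffill().bfill()


def moving_mean(series: pd.Series, window: int) -> pd.Series:
    """Centred moving mean over the available samples in the window."""
    if window < 1:
        raise ValueError("window must be >= 1")
    return series.rolling(window, center=True, min_periods=1).mean()


@dataclass
class TrendResult:
    """OLS trend of one series: slope per decade, p-value, significance mask."""

    slope: float
    p_value: float
    masked: bool


@dataclass
class TrendField:
    """Per-pixel decadal trends with a p >= 0.05 significance mask."""

    grid: object
    slope: np.ndarray    # units per decade
    p_value: np.ndarray
    masked: np.ndarray   # True where p >= 0.05


_P_MASK = 0.05


def _ols_trend(t_decades: np.ndarray, y: np.ndarray):
    """Vectorised OLS of y (nt, ...) on t (nt,); NaN-aware per pixel."""
    valid = ~np.isnan(y)
    n = valid.sum(axis=0)
    t = t_decades.reshape((-1,) + (1,) * (y.ndim - 1))
    tv = np.where(valid, t, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mean = np.nanmean(tv, axis=0)
        y_mean = np.nanmean(y, axis=0)
        dt = np.where(valid, t - t_mean, 0.0)
        dy = np.where(valid, y - y_mean, 0.0)
        sxx = (dt**2).sum(axis=0)
        sxy = (dt * dy).sum(axis=0)
        slope = sxy / sxx
        resid = np.where(valid, dy - slope * dt, 0.0)
        rss = (resid**2).sum(axis=0)
        dof = n - 2
        sigma2 = rss / np.maximum(dof, 1)
        se = np.sqrt(sigma2 / sxx)
        tstat = np.where(se > 0, np.abs(slope) / se, np.inf)
    p = np.where(
        np.isfinite(tstat),
        2 * stats.t.sf(np.where(np.isfinite(tstat), tstat, 0.0), np.maximum(dof, 1)),
        0.0,
    )
    # a perfectly constant pixel: slope 0, se 0 -> no evidence of trend
    p = np.where((se == 0) & (slope == 0), 1.0, p)
    slope = np.where(n >= 2, slope, np.nan)
    p = np.where(n >= 2, p, np.nan)
    return slope, p


def _time_in_decades(times: pd.DatetimeIndex) -> np.ndarray:
    months = (times.year - times.year[0]) * 12 + (times.month - times.month[0])
    return np.asarray(months, dtype=float) / 120.0


def decadal_trend(obj):
    """Least-squares trend (units per decade) with per-pixel p-value masking.

    For a monthly :class:`GeoField` returns a :class:`TrendField`; for a
    series returns a :class:`TrendResult`. Pixels with p >= 0.05 are masked
    (the trend is not distinguishable from zero at the 5% level). P-values
    are from the classical t-statistic of the OLS slope, without serial
    autocorrelation correction.
    """
    times, values = _obj_times_values(obj)
    if len(times) < 24:
        raise ValueError("need at least 24 monthly samples for a decadal trend")
    t_decades = _time_in_decades(times)
    slope, p = _ols_trend(t_decades, values)
    if isinstance(obj, pd.Series):
        return TrendResult(slope=float(slope), p_value=float(p), masked=bool(p >= _P_MASK))
    return TrendField(grid=obj.grid, slope=slope, p_value=p, masked=p >= _P_MASK)


def total_wet_deposition(bins) -> pd.Series:
    """Total deposition flux: elementwise sum of the five size-bin series.

    A time step is missing if any bin is missing there.
    """
    series_list = [pd.Series(b) for b in bins]
    if len(series_list) != 5:
        raise ValueError(f"expected 5 size-bin series, got {len(series_list)}")
    index = series_list[0].index
    for s in series_list[1:]:
        if not s.index.equals(index):
            raise ValueError("size-bin series are not aligned on the same time axis")
    stacked = pd.concat(series_list, axis=1)
    return stacked.sum(axis=1, skipna=False).rename("total_wet_deposition")
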