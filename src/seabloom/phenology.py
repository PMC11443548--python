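"""Bloom phenology from 8-day chlorophyll series.

The detector follows the threshold-referenced cumulative-sum-of-anomalies
method: the threshold is the long-term median of the full multi-year
series raised by a fixed percentage (20% by default); anomalies are the
series minus the threshold, and their cumulative sum rises exactly while
the series sits above threshold. Bloom initiation is the first 8-day step
above threshold within a season window, the peak is the (first) seasonal
maximum, termination is the first step below threshold after the peak,
and duration is the number of 8-day periods between initiation and
termination. Season windows run October through May so that the austral
spring/summer growth period is isolated from any secondary winter bloom.

Working on the cumulative sum and working on direct threshold crossings
are algebraically the same: the first difference of the cumulative sum is
the anomaly itself, so a sign change of the gradient *is* a threshold
crossing. Both formulations are exposed and tested for equality.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GeoField, Region, region_mean, resample_time


@dataclass(frozen=True)
class PhenoConfig:
    """Detector settings.

    threshold_percent: fractional elevation over the long-term median
        (0.20 means median x 1.2). Alternatives of 0.05-0.15 are in use
        elsewhere and can be set here.
    season_start_month / season_end_month: bounds of the growth-season
        window (October..May isolates austral spring and summer).
    """

    threshold_percent: float = 0.20
    season_start_month: int = 10
    season_end_month: int = 5

    def __post_init__(self):
        if not 0 <= self.threshold_percent < 1:
            raise ValueError("threshold_percent must be in [0, 1)")
        if self.season_start_month == self.season_end_month:
            raise ValueError("season window is empty")


@dataclass
class PhenoMetrics:
    """Timing metrics for one growth season (indices are window-relative)."""

    season: str
    detected: bool
    initiation: int | None = None
    peak: int | None = None
    termination: int | None = None
    duration: int | None = None
    initiation_date: pd.Timestamp | None = None
    peak_date: pd.Timestamp | None = None
    termination_date: pd.Timestamp | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class SeasonWindow:
    label: str
    series: pd.Series
    complete: bool


def compute_threshold(series: pd.Series, config: PhenoConfig = PhenoConfig()) -> float:
    """Threshold criterion: median of the entire series times (1 + percent).

    Computed once from the full multi-year record, not per season. The
    series must be gap-free (run :func:`~seabloom.climatology.fill_gaps_linear`
    first).
    """
    values = series.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a threshold from an empty series")
    if np.isnan(values).any():
        raise ValueError("series has gaps; fill them before computing the threshold")
    return float(np.median(values)) * (1.0 + config.threshold_percent)


def cumulative_anomaly(series: pd.Series, threshold: float) -> pd.Series:
    """Running sum of (x_t - threshold); rises exactly while x_t > threshold."""
    values = series.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("series has gaps; fill them before cumulative sums")
    return pd.Series(np.cumsum(values - threshold), index=series.index, name="cumsum_anomaly")


def detect_phenology(
    window: pd.Series,
    threshold: float,
    season_label: str = "",
) -> PhenoMetrics:
    """Initiation, peak, termination and duration for one season window.

    Initiation is the first step with x > threshold (equivalently, the
    first positive gradient of the cumulative anomaly sum). The peak is the
    first occurrence of the seasonal maximum. Termination is the first step
    after the peak with x < threshold. If the series never exceeds the
    threshold the result carries ``detected=False`` rather than raising;
    degenerate windows (entirely above threshold, or never dropping below
    it after the peak) are detected but flagged.
    """
    x = window.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("season window has gaps; fill them before detection")
    above = x > threshold
    if not above.any():
        return PhenoMetrics(season=season_label, detected=False, flags=["no-bloom-detected"])
    flags: list[str] = []
    initiation = int(np.argmax(above))
    if above.all():
        flags.append("starts-above-threshold")
    peak = int(np.argmax(x))  # first occurrence of the maximum
    after_peak_below = (x < threshold) & (np.arange(x.size) > peak)
    if after_peak_below.any():
        termination = int(np.argmax(after_peak_below))
    else:
        termination = x.size - 1
        flags.append("terminates-at-window-end")
    return PhenoMetrics(
        season=season_label,
        detected=True,
        initiation=initiation,
        peak=peak,
        termination=termination,
        duration=termination - initiation,
        initiation_date=window.index[initiation],
        peak_date=window.index[peak],
        termination_date=window.index[termination],
        flags=flags,
    )


def season_windows(series: pd.Series, config: PhenoConfig = PhenoConfig()) -> list[SeasonWindow]:
    """Split a multi-year 8-day series into October-May season windows.

    Season ``y/y+1`` runs from the first step starting in October of year
    ``y`` through the last step starting in May of year ``y+1``. Windows
    missing either end of that span are flagged incomplete. Steps are never
    split: membership is by the step start date.
    """
    idx = pd.DatetimeIndex(series.index)
    months = idx.month
    years = idx.year
    start_m, end_m = config.season_start_month, config.season_end_month
    windows: list[SeasonWindow] = []
    for y in range(int(years.min()) - 1, int(years.max()) + 1):
        in_window = ((years == y) & (months >= start_m)) | ((years == y + 1) & (months <= end_m))
        if not in_window.any():
            continue
        sub = series[in_window]
        complete = bool(
            ((years == y) & (months == start_m)).any()
            and ((years == y + 1) & (months == end_m)).any()
        )
        windows.append(SeasonWindow(label=f"{y}/{y + 1}", series=sub, complete=complete))
    return windows


def run_phenology(
    series: pd.Series,
    config: PhenoConfig = PhenoConfig(),
    include_partial: bool = False,
) -> tuple[float, list[PhenoMetrics]]:
    """Threshold + per-season detection over a full gap-free 8-day series.

    Detection runs on every season and reports a detected/not-detected flag
    per season, which replaces any externally supplied list of bloom years
    with a reproducible rule.
    """
    threshold = compute_threshold(series, config)
    metrics = []
    for win in season_windows(series, config):
        if not win.complete and not include_partial:
            continue
        m = detect_phenology(win.series, threshold, season_label=win.label)
        if not win.complete:
            m.flags.append("partial-season")
        metrics.append(m)
    return threshold, metrics


def metrics_to_frame(metrics: list[PhenoMetrics]) -> pd.DataFrame:
    """Tabulate per-season metrics for CSV export."""
    rows = []
    for m in metrics:
        rows.append(
            {
                "season": m.season,
                "detected": m.detected,
                "initiation_date": m.initiation_date,
                "peak_date": m.peak_date,
                "termination_date": m.termination_date,
                "duration_8day": m.duration,
                "flags": ";".join(m.flags),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BoxScanResult:
    """Region-mean series for every fully contained box position."""

    corners: list[tuple[float, float]]  # (lat_min, lon_min) per box
    series: dict[tuple[float, float], pd.Series]
    box_size: float
    stride: float

    @property
    def n_positions(self) -> int:
        return len(self.corners)


def box_scan(
    geofield: GeoField,
    domain: Region,
    box_size: float = 5.0,
    stride: float = 1.0,
    monthly: bool = False,
    weighting: str = "cos-lat",
) -> BoxScanResult:
    """Slide a box across the domain and average the field inside each position.

    The box starts at the domain corner and moves in ``stride``-degree
    increments east and south; only positions fully contained in the domain
    are used. For a domain of spans (La, Lo) the count is
    ``((La - box)/stride + 1) * ((Lo - box)/stride + 1)`` for integer fits.
    """
    lat_span = domain.lat_max - domain.lat_min
    lon_span = domain.lon_max - domain.lon_min
    if box_size > lat_span or box_size > lon_span:
        raise ValueError("box is larger than the domain")
    eps = 1e-9
    lat0s = np.arange(domain.lat_min, domain.lat_max - box_size + eps, stride)
    lon0s = np.arange(domain.lon_min, domain.lon_max - box_size + eps, stride)
    corners = []
    series = {}
    for lat0 in lat0s:
        for lon0 in lon0s:
            box = Region(lat0, lat0 + box_size, lon0, lon0 + box_size)
            s = region_mean(geofield, box, weighting=weighting)
            if monthly:
                s = resample_time(s, "monthly")
            key = (round(float(lat0), 6), round(float(lon0), 6))
            corners.append(key)
            series[key] = s
    return BoxScanResult(corners=corners, series=series, box_size=box_size, stride=stride)
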