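"""Synthetic inputs with recorded ground truth.

Every generator emulates one class of observational input the analysis
stages consume — 8-day chlorophyll composites with cloud gaps, sea-level
anomaly fields with planted Gaussian eddies, thermocline profiles with a
known mixed-layer depth, daily event series, and monthly trend fields —
and returns the planted truth alongside, so recovery by the downstream
stage can be scored without re-reading generator internals.

Noise models follow the standard choices for each observable:
multiplicative lognormal for chlorophyll (positive-definite), additive
Gaussian for sea level and temperature. All randomness in one call flows
from a single seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calendars import STEPS_PER_YEAR, eight_day_dates
from .grids import GeoField, GeoGrid

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = 111.32
GRAVITY = 9.81  # m s-2
OMEGA = 7.2921e-5  # rad s-1


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BloomTruth:
    """One planted bloom on the 8-day calendar.

    Steps ``initiation_index .. termination_index - 1`` are elevated above
    the baseline; ``termination_index`` is the first step back at baseline,
    matching the phenology definition of termination as the first step
    below threshold after the peak.
    """

    initiation_index: int
    termination_index: int
    peak_index: int
    amplitude: float  # mg m-3 above baseline
    baseline: float   # mg m-3
    season_label: str = ""

    def __post_init__(self):
        if not self.initiation_index <= self.peak_index < self.termination_index:
            raise ValueError(
                "require initiation_index <= peak_index < termination_index "
                f"(got {self.initiation_index}, {self.peak_index}, {self.termination_index})"
            )
        if self.amplitude <= 0 or self.baseline <= 0:
            raise ValueError("amplitude and baseline must be positive")


@dataclass(frozen=True)
class EddyTruth:
    """One planted Gaussian eddy: anticyclonic <=> positive SLA extremum."""

    center_lat: float
    center_lon: float
    amplitude: float  # m, signed SLA extremum
    radius: float     # km, Gaussian sigma

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.amplitude == 0:
            raise ValueError("amplitude must be nonzero")

    @property
    def polarity(self) -> str:
        return "anticyclonic" if self.amplitude > 0 else "cyclonic"


@dataclass(frozen=True)
class ProfileTruth:
    mld_true: float          # m, where the 0.2 degC drop from the surface occurs
    surface_temp: float      # degC
    thermocline_width: float  # m, tanh e-folding scale

    def __post_init__(self):
        if self.mld_true <= 10:
            raise ValueError("mld_true must lie below the 10 m reference depth")
        if self.thermocline_width <= 0:
            raise ValueError("thermocline_width must be positive")


@dataclass(frozen=True)
class TrendTruth:
    slope: float      # units per decade
    intercept: float  # units
    noise_sd: float   # units

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def write_truth(truth, path) -> None:
    """Serialise one truth record or a list of them as a JSON sidecar."""
    if isinstance(truth, (list, tuple)):
        payload = [dataclasses.asdict(t) for t in truth]
    else:
        payload = dataclasses.asdict(truth)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# chlorophyll series
# ---------------------------------------------------------------------------

def make_chl_series(
    n_years: int,
    baseline: float,
    blooms: list[BloomTruth],
    gap_fraction: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    start_year: int = 1998,
    blocked_gaps: bool = False,
    peak_boost: float = 0.1,
) -> tuple[pd.Series, list[BloomTruth]]:
    """8-day chlorophyll series with planted blooms, noise and cloud gaps.

    ``baseline`` is either a constant (mg m-3) or a length-46 per-step
    seasonal cycle, tiled over the years; oligotrophic subtropical records
    carry a modest austral-winter elevation from deep winter mixing, which
    is what the seasonal form emulates. Each bloom elevates steps
    ``[initiation_index, termination_index)`` above the local baseline by
    its amplitude, with an extra ``peak_boost * amplitude`` at the peak step
    so the seasonal maximum is unique. Noise is multiplicative lognormal
    with coefficient of variation ``noise_cv``; ``gap_fraction`` of the
    steps are masked (NaN), at random by default or in contiguous runs when
    ``blocked_gaps`` is set to emulate cloud cover. Planted bloom windows
    always retain at least one unmasked step.
    """
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must be in [0, 1)")
    if n_years < 2:
        raise ValueError("n_years must be >= 2")
    n = n_years * STEPS_PER_YEAR
    windows = sorted((b.initiation_index, b.termination_index) for b in blooms)
    for (s0, e0), (s1, _e1) in zip(windows, windows[1:]):
        if s1 < e0:
            raise ValueError(
                f"overlapping bloom windows: [{s0}, {e0}) and starting at {s1}"
            )
    for b in blooms:
        if not (0 <= b.initiation_index and b.termination_index <= n):
            raise ValueError("bloom window extends outside the series")

    base = np.asarray(baseline, dtype=float)
    if base.ndim == 0:
        values = np.full(n, float(base))
    elif base.shape == (STEPS_PER_YEAR,):
        values = np.tile(base, n_years)
    else:
        raise ValueError("baseline must be a scalar or a length-46 seasonal cycle")
    if np.any(values <= 0):
        raise ValueError("baseline must be positive everywhere")
    for b in blooms:
        values[b.initiation_index:b.termination_index] += b.amplitude
        values[b.peak_index] += b.amplitude * peak_boost

    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        values = values * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n)

    n_gaps = int(round(gap_fraction * n))
    if n_gaps > 0:
        for _ in range(100):
            if blocked_gaps:
                gap_idx = _blocked_gap_indices(rng, n, n_gaps)
            else:
                gap_idx = rng.choice(n, size=n_gaps, replace=False)
            hit = np.zeros(n, dtype=bool)
            hit[gap_idx] = True
            if all(not hit[b.initiation_index:b.termination_index].all() for b in blooms):
                values = values.copy()
                values[gap_idx] = np.nan
                break
        else:  # pragma: no cover - astronomically unlikely at sane gap fractions
            raise RuntimeError("could not place gaps without erasing a planted bloom")

    series = pd.Series(values, index=eight_day_dates(start_year, n_years), name="chl")
    return series, list(blooms)


def _blocked_gap_indices(rng, n: int, n_gaps: int, run_length: int = 4) -> np.ndarray:
    """Contiguous masked runs totalling ``n_gaps`` steps."""
    idx: set[int] = set()
    while len(idx) < n_gaps:
        start = int(rng.integers(0, n))
        for k in range(start, min(start + run_length, n)):
            if len(idx) < n_gaps:
                idx.add(k)
    return np.fromiter(idx, dtype=int)


def make_bloom_study_series(
    seed: int,
    n_years: int = 24,
    start_year: int = 1997,
    gap_fraction: float = 0.2,
    noise_cv: float = 0.1,
) -> tuple[pd.Series, list[BloomTruth]]:
    """Multi-decade chlorophyll record under the study conditions.

    One austral-summer bloom per season: initiation in November, duration
    9-14 eight-day steps, amplitude 0.2 mg m-3 over a 0.1 mg m-3 summer
    baseline. The baseline carries a winter secondary elevation (deep
    winter mixing), which keeps the long-term median — and hence the
    detection threshold — above the summer background, as in the real
    record where the October-May window isolates the summer bloom from
    winter growth.
    """
    rng = np.random.default_rng(seed)
    baseline = np.full(STEPS_PER_YEAR, 0.10)
    baseline[19:31] = 0.14  # austral winter (Jun-Aug) elevation
    blooms = []
    for y in range(n_years - 1):
        init = y * STEPS_PER_YEAR + int(rng.integers(39, 43))  # November
        dur = int(rng.integers(9, 15))
        peak = init + int(rng.integers(1, dur - 1))
        blooms.append(
            BloomTruth(init, init + dur, peak, amplitude=0.2, baseline=0.10,
                       season_label=str(start_year + y))
        )
    return make_chl_series(
        n_years, baseline, blooms, gap_fraction=gap_fraction,
        noise_cv=noise_cv, seed=seed, start_year=start_year,
    )


# ---------------------------------------------------------------------------
# SLA fields, geostrophic currents
# ---------------------------------------------------------------------------

def make_sla_field(
    grid: GeoGrid,
    eddies: list[EddyTruth],
    noise_sd: float = 0.0,
    seed: int = 0,
    times=None,
) -> tuple[GeoField, list[EddyTruth]]:
    """Sea-level-anomaly field as a sum of Gaussian bumps plus noise.

    Each eddy contributes ``A * exp(-d^2 / (2 r^2))`` with ``d`` the
    local-tangent-plane distance (km) to its centre. The same eddies are
    planted at every time step.
    """
    if times is None:
        times = pd.DatetimeIndex([pd.Timestamp("2019-12-01")])
    times = pd.DatetimeIndex(times)
    lat2d, lon2d = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    sla = np.zeros(grid.shape)
    for e in eddies:
        if not (grid.lats.min() <= e.center_lat <= grid.lats.max()
                and grid.lons.min() <= e.center_lon <= grid.lons.max()):
            raise ValueError(f"eddy centre ({e.center_lat}, {e.center_lon}) outside grid")
        dy = (lat2d - e.center_lat) * KM_PER_DEG
        dx = (lon2d - e.center_lon) * KM_PER_DEG * np.cos(np.deg2rad(e.center_lat))
        sla += e.amplitude * np.exp(-(dx**2 + dy**2) / (2 * e.radius**2))
    rng = np.random.default_rng(seed)
    cube = np.broadcast_to(sla, (len(times),) + grid.shape).copy()
    if noise_sd > 0:
        cube = cube + rng.normal(0.0, noise_sd, size=cube.shape)
    return GeoField(grid=grid, times=times, values=cube, units="m", name="sla"), list(eddies)


def make_geostrophic_currents(sla: GeoField) -> tuple[GeoField, GeoField]:
    """Surface geostrophic currents from SLA by centred differences.

    u = -(g/f) dEta/dy, v = (g/f) dEta/dx with f = 2 Omega sin(lat).
    The outermost ring of cells (one-sided differences) is flagged missing.
    Grids touching the equatorial band (|lat| <= 5 deg) are rejected since
    the geostrophic balance degenerates as f -> 0.
    """
    lats = sla.grid.lats
    if np.abs(lats).min() <= 5.0:
        raise ValueError("grid reaches |lat| <= 5 deg where f -> 0; geostrophy invalid")
    f = 2 * OMEGA * np.sin(np.deg2rad(lats))  # s-1, per row
    dy = np.deg2rad(np.abs(np.diff(lats)).mean()) * EARTH_RADIUS_KM * 1e3
    if lats[0] > lats[-1]:  # descending latitude axis: d/dy = -d/drow
        dy = -dy
    dx_row = (
        np.deg2rad(np.abs(np.diff(sla.grid.lons)).mean())
        * EARTH_RADIUS_KM * 1e3 * np.cos(np.deg2rad(lats))
    )
    deta_dy = np.gradient(sla.values, axis=1) / dy
    deta_dx = np.gradient(sla.values, axis=2) / dx_row[None, :, None]
    gf = GRAVITY / f[None, :, None]
    u = -gf * deta_dy
    v = gf * deta_dx
    for arr in (u, v):
        arr[:, 0, :] = np.nan
        arr[:, -1, :] = np.nan
        arr[:, :, 0] = np.nan
        arr[:, :, -1] = np.nan
    mk = lambda vals, nm: GeoField(grid=sla.grid, times=sla.times, values=vals, units="m s-1", name=nm)
    return mk(u, "u"), mk(v, "v")


# ---------------------------------------------------------------------------
# temperature profiles
# ---------------------------------------------------------------------------

def make_profile(
    truth: ProfileTruth,
    dz: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    deep_drop: float = 8.0,
    max_depth: float | None = None,
):
    """Vertical temperature profile with a tanh thermocline.

    The water column is isothermal at ``surface_temp`` down to the top of
    the thermocline, then declines as a tanh of total amplitude
    ``deep_drop``. The top is placed so the temperature first falls 0.2 degC
    below the surface value exactly at ``mld_true``.
    """
    from .mixedlayer import Profile  # local import to avoid a cycle

    if dz <= 0:
        raise ValueError("dz must be positive")
    w = truth.thermocline_width
    z_top = truth.mld_true - w * np.arctanh(0.2 / deep_drop)
    if max_depth is None:
        max_depth = max(200.0, truth.mld_true + 6 * w)
    depth = np.arange(0.0, max_depth + dz, dz)
    temp = truth.surface_temp - deep_drop * np.tanh(np.clip(depth - z_top, 0, None) / w)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        temp = temp + rng.normal(0.0, noise_sd, size=temp.size)
    return Profile(depth=depth, temperature=temp, qc=np.ones(depth.size, dtype=int))


# ---------------------------------------------------------------------------
# daily event series, trend fields
# ---------------------------------------------------------------------------

def make_event_series(
    n_days: int,
    base_level: float,
    events: list[tuple[int, int, float]],
    seed: int = 0,
    noise_sd: float = 0.0,
    start: str = "2003-01-01",
) -> pd.Series:
    """Daily series with step elevations of (start, length, magnitude) events."""
    values = np.full(n_days, float(base_level))
    for start_day, length, magnitude in events:
        if start_day < 0 or start_day + length > n_days:
            raise ValueError(f"event ({start_day}, {length}) outside the series")
        values[start_day:start_day + length] += magnitude
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_days)
    index = pd.date_range(start, periods=n_days, freq="D")
    return pd.Series(values, index=index, name="event_series")


def make_trend_field(
    grid: GeoGrid,
    truth: TrendTruth,
    n_months: int,
    seed: int = 0,
    start: str = "1980-01-01",
) -> tuple[GeoField, TrendTruth]:
    """Monthly field where every pixel follows intercept + slope*t + noise."""
    if n_months < 24:
        raise ValueError("n_months must be >= 24")
    times = pd.date_range(start, periods=n_months, freq="MS")
    t_decades = np.arange(n_months) / 120.0
    base = truth.intercept + truth.slope * t_decades
    rng = np.random.default_rng(seed)
    cube = np.broadcast_to(base[:, None, None], (n_months,) + grid.shape).copy()
    if truth.noise_sd > 0:
        cube = cube + rng.normal(0.0, truth.noise_sd, size=cube.shape)
    return GeoField(grid=grid, times=times, values=cube, units="", name="trend_field"), truth


# ---------------------------------------------------------------------------
# anomaly-pipeline helpers
# ---------------------------------------------------------------------------

def plant_standardized_excursion(
    series: pd.Series,
    clim,
    dates,
    magnitude_sd: float,
) -> pd.Series:
    """Overwrite ``dates`` with values exactly ``magnitude_sd`` climatological
    standard deviations from the climatological mean of each date's period.

    The climatology must be built on a reference period that excludes the
    planted dates, so the excursion has a well-defined magnitude in SD units.
    """
    from .climatology import _period_lookup

    out = series.copy()
    dates = pd.DatetimeIndex(dates)
    mean, sd, flagged = _period_lookup(clim, dates)
    if np.isnan(mean).any() or np.isnan(sd).any() or flagged.any():
        raise ValueError("climatology is undefined or undersampled at the planted dates")
    out.loc[dates] = mean + magnitude_sd * sd
    return out
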