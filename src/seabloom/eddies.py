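"""Mesoscale eddy detection from sea-level anomaly and eddy kinetic energy.

Eddies are detected per SLA time slice from closed contours: for each
local extremum, contour levels are walked from the extremum toward the
background in fixed increments; a level is accepted while a closed
contour encloses the extremum and no second extremum, so SLA changes
monotonically outward by construction. The innermost accepted contour
defines the centre (anomaly-weighted mass centre of its cells), the
outermost defines the edge. Anticyclones are SLA maxima and cyclones SLA
minima (Southern Hemisphere convention). The numeric criteria (contour
increment, minimum amplitude, edge area bounds) are configuration, with
defaults in the range conventional for ~25 km altimetry products.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure

from .grids import GeoField, Region

KM_PER_DEG = 111.32


@dataclass(frozen=True)
class EddyCriteria:
    """Detection criteria for closed-contour eddy identification."""

    contour_interval: float = 0.01   # m between successive SLA contour levels
    min_amplitude: float = 0.02      # m, |extremum - edge level| floor
    min_area_cells: float = 8.0      # edge-enclosed area, grid cells
    max_area_cells: float = 1000.0
    extremum_window: int = 2         # half-width of the local-extremum window
    max_levels: int = 200
    weighted_center: bool = True     # SLA-anomaly-weighted vs plain centroid
    min_center_cells: float = 12.0   # smallest contour area used for the mass centre


@dataclass
class EddyRecord:
    """One detected eddy."""

    center_lat: float
    center_lon: float
    polarity: str                 # "cyclonic" | "anticyclonic"
    amplitude: float              # m, SLA at extremum minus SLA at edge (>0)
    edge: np.ndarray              # closed polygon, rows of (lat, lon)
    equivalent_radius: float      # km, radius of the circle with the edge's area
    time: pd.Timestamp | None = None


@dataclass
class EddyCensus:
    """All detections for one time slice, tallied by polarity."""

    time: pd.Timestamp | None
    records: list[EddyRecord] = field(default_factory=list)

    @property
    def n_cyclonic(self) -> int:
        return sum(r.polarity == "cyclonic" for r in self.records)

    @property
    def n_anticyclonic(self) -> int:
        return sum(r.polarity == "anticyclonic" for r in self.records)


def eke(u: GeoField, v: GeoField) -> GeoField:
    """Eddy kinetic energy (1/2)(u^2 + v^2); missing where either input is."""
    if u.grid != v.grid:
        raise ValueError("u and v are on different grids")
    if not u.times.equals(v.times):
        raise ValueError("u and v have different time axes")
    values = 0.5 * (u.values**2 + v.values**2)
    return GeoField(grid=u.grid, times=u.times, values=values, units="m2 s-2", name="eke")


def _local_extrema(sla2d: np.ndarray, criteria: EddyCriteria) -> list[tuple[int, int, float]]:
    """Candidate extrema: local max/min in a (2w+1)^2 window with |SLA|
    above the amplitude floor. Same-sign candidates closer than the
    suppression radius are noise sub-peaks of one core: only the strongest
    survives. Returns (row, col, value)."""
    size = 2 * criteria.extremum_window + 1
    out = []
    for sign in (1.0, -1.0):
        f = sign * sla2d
        peak = ndimage.maximum_filter(f, size=size, mode="nearest")
        cand = [
            (int(r), int(c), float(sla2d[r, c]))
            for r, c in zip(*np.nonzero((f >= peak) & (f >= criteria.min_amplitude)))
        ]
        cand.sort(key=lambda rc: -abs(rc[2]))
        kept: list[tuple[int, int, float]] = []
        for r, c, v in cand:
            if all(max(abs(r - kr), abs(c - kc)) > size for kr, kc, _ in kept):
                kept.append((r, c, v))
        out.extend(kept)
    return out


def _closed_contour_enclosing(sla2d, level, point):
    """The closed find_contours polygon at ``level`` containing ``point``."""
    for contour in measure.find_contours(sla2d, level):
        if not np.allclose(contour[0], contour[-1]):
            continue  # open contour (hits the domain boundary)
        if contour.shape[0] < 4:
            continue
        poly = Polygon(contour)
        if not poly.is_valid:
            continue
        if poly.contains(shapely.Point(point)):
            return contour, poly
    return None, None


def detect_eddies(
    sla: GeoField | np.ndarray,
    criteria: EddyCriteria = EddyCriteria(),
    shallow_mask: np.ndarray | None = None,
    grid=None,
    time=None,
) -> EddyCensus:
    """Closed-contour eddy detection on a single SLA time slice.

    ``sla`` may be a single-time :class:`~seabloom.grids.GeoField` or a 2-D
    array with ``grid`` supplied. ``shallow_mask`` (True = shallow, e.g.
    shallower than 200 m) discards detections whose edge touches masked
    cells. An all-missing slice yields an empty census.
    """
    if isinstance(sla, GeoField):
        if sla.values.shape[0] != 1:
            raise ValueError("detect_eddies wants a single time slice; use census_series")
        grid = sla.grid
        time = sla.times[0] if time is None else time
        sla2d = sla.values[0]
    else:
        if grid is None:
            raise ValueError("grid is required when passing a raw array")
        sla2d = np.asarray(sla, dtype=float)

    census = EddyCensus(time=time)
    if np.isnan(sla2d).all():
        return census
    work = np.nan_to_num(sla2d, nan=0.0)

    extrema = _local_extrema(work, criteria)
    extrema_pts = [(r, c) for r, c, _v in extrema]
    step = criteria.contour_interval

    for r0, c0, h in extrema:
        sign = 1.0 if h > 0 else -1.0
        f = sign * work  # extremum is a maximum of f
        peak_val = sign * h
        accepted: list[tuple[float, np.ndarray, Polygon]] = []
        # walk levels from just below the extremum toward the background
        k0 = int(np.floor((peak_val - 1e-12) / step))
        for k in range(k0, k0 - criteria.max_levels, -1):
            level = k * step
            if level >= peak_val:
                continue
            if level <= f.min():
                break  # no closed contour can exist at or below the field minimum
            contour, poly = _closed_contour_enclosing(f, level, (r0, c0))
            if poly is None:
                break
            others = [
                p for p in extrema_pts
                if p != (r0, c0) and poly.contains(shapely.Point(p))
            ]
            if others:
                break  # contour would merge two cores: stop growing
            if poly.area > criteria.max_area_cells:
                break
            accepted.append((level, contour, poly))
        if not accepted:
            continue
        edge_level, edge_contour, edge_polygon = accepted[-1]
        amplitude = peak_val - edge_level
        if amplitude < criteria.min_amplitude:
            continue
        if edge_polygon.area < criteria.min_area_cells:
            continue
        if shallow_mask is not None and _touches_mask(edge_polygon, shallow_mask):
            continue
        # mass centre on the innermost contour with enough cell support that
        # measurement noise averages out
        center_level, _ctr, center_poly = next(
            (a for a in accepted if a[2].area >= criteria.min_center_cells),
            accepted[-1],
        )
        center_rc = _mass_center(f, center_poly, center_level, criteria.weighted_center)
        lat_c = _interp_axis(grid.lats, center_rc[0])
        lon_c = _interp_axis(grid.lons, center_rc[1])
        census.records.append(
            EddyRecord(
                center_lat=lat_c,
                center_lon=lon_c,
                polarity="anticyclonic" if sign > 0 else "cyclonic",
                amplitude=float(amplitude),
                edge=_contour_to_lonlat(edge_contour, grid),
                equivalent_radius=_equivalent_radius_km(edge_polygon, grid, lat_c),
                time=time,
            )
        )
    return census


def _touches_mask(poly: Polygon, shallow_mask: np.ndarray) -> bool:
    rmin, cmin, rmax, cmax = (
        int(np.floor(poly.bounds[0])), int(np.floor(poly.bounds[1])),
        int(np.ceil(poly.bounds[2])), int(np.ceil(poly.bounds[3])),
    )
    rr, cc = np.meshgrid(
        np.arange(max(rmin, 0), min(rmax + 1, shallow_mask.shape[0])),
        np.arange(max(cmin, 0), min(cmax + 1, shallow_mask.shape[1])),
        indexing="ij",
    )
    inside = shapely.contains_xy(poly, rr.ravel(), cc.ravel())
    return bool(shallow_mask[rr.ravel()[inside], cc.ravel()[inside]].any())


def _mass_center(f: np.ndarray, poly: Polygon, level: float, weighted: bool):
    rmin, cmin, rmax, cmax = poly.bounds
    rr, cc = np.meshgrid(
        np.arange(int(np.floor(rmin)), int(np.ceil(rmax)) + 1),
        np.arange(int(np.floor(cmin)), int(np.ceil(cmax)) + 1),
        indexing="ij",
    )
    inside = shapely.contains_xy(poly, rr.ravel(), cc.ravel())
    rows = rr.ravel()[inside]
    cols = cc.ravel()[inside]
    if rows.size == 0:  # contour tighter than one cell: fall back to vertices
        verts = np.asarray(poly.exterior.coords)
        return float(verts[:, 0].mean()), float(verts[:, 1].mean())
    if weighted:
        w = np.clip(f[rows, cols] - level, 0.0, None)
        if w.sum() <= 0:
            w = np.ones_like(w)
    else:
        w = np.ones(rows.size)
    return float((rows * w).sum() / w.sum()), float((cols * w).sum() / w.sum())


def _interp_axis(axis: np.ndarray, idx: float) -> float:
    i0 = int(np.clip(np.floor(idx), 0, axis.size - 2))
    frac = idx - i0
    return float(axis[i0] + frac * (axis[i0 + 1] - axis[i0]))


def _contour_to_lonlat(contour: np.ndarray, grid) -> np.ndarray:
    lats = np.array([_interp_axis(grid.lats, r) for r in contour[:, 0]])
    lons = np.array([_interp_axis(grid.lons, c) for c in contour[:, 1]])
    return np.column_stack([lats, lons])


def _equivalent_radius_km(poly: Polygon, grid, lat_c: float) -> float:
    cell_km2 = (grid.dlat * KM_PER_DEG) * (grid.dlon * KM_PER_DEG * np.cos(np.deg2rad(lat_c)))
    return float(np.sqrt(poly.area * cell_km2 / np.pi))


def census_series(
    sla: GeoField,
    region: Region | None = None,
    criteria: EddyCriteria = EddyCriteria(),
    shallow_mask: np.ndarray | None = None,
) -> list[EddyCensus]:
    """Per-time eddy censuses; an eddy counts toward a region if its
    centre lies inside (edge overlap alone does not count)."""
    out = []
    for k, t in enumerate(sla.times):
        census = detect_eddies(
            sla.values[k], criteria=criteria, shallow_mask=shallow_mask,
            grid=sla.grid, time=t,
        )
        if region is not None:
            census.records = [
                r for r in census.records
                if region.contains(r.center_lat, r.center_lon)
            ]
        out.append(census)
    return out


def census_to_frame(censuses: list[EddyCensus]) -> pd.DataFrame:
    """Tabulate polarity counts per time for CSV export."""
    return pd.DataFrame(
        {
            "time": [c.time for c in censuses],
            "n_cyclonic": [c.n_cyclonic for c in censuses],
            "n_anticyclonic": [c.n_anticyclonic for c in censuses],
        }
    )


def records_to_geojson(censuses: list[EddyCensus]) -> dict:
    """Eddy edges as a GeoJSON FeatureCollection (lon/lat polygons)."""
    features = []
    for census in censuses:
        for r in census.records:
            ring = [[float(lon), float(lat)] for lat, lon in r.edge]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "time": str(r.time),
                        "polarity": r.polarity,
                        "amplitude_m": r.amplitude,
                        "equivalent_radius_km": r.equivalent_radius,
                        "center": [float(r.center_lon), float(r.center_lat)],
                    },
                }
            )
    return {"type": "FeatureCollection", "features": features}
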