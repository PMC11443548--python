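"""Chlorophyll fluorescence quantum yield, an iron-stress proxy.

The quantum yield is the ratio of the fluorescence emitted by
phytoplankton (inferred from the normalized fluorescence line height,
nFLH) to the radiation they absorb (instantaneous irradiance iPAR times
a chlorophyll-specific absorption power law). Iron stress raises the
yield, so standardized *negative* anomalies of phi_f mark relief from
iron limitation. The anomaly step delegates to the generic standardized
anomaly machinery — there is no special-casing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climatology import Climatology, standardized_anomaly
from .grids import GeoField
from .mixedlayer import optics_config


@dataclass
class FluorInputs:
    """Co-registered satellite inputs for the quantum-yield computation.

    nflh: W m-2 um-1 sr-1; ipar: uEin m-2 s-1; chl: mg m-3;
    par (Ein m-2 day-1) is carried along for screening but does not enter
    the default formula.
    """

    nflh: np.ndarray
    ipar: np.ndarray
    chl: np.ndarray
    par: np.ndarray | None = None


def phi_f(inputs, config: dict | None = None):
    """Fluorescence quantum yield (dimensionless, arbitrary common scale).

    phi_f = scale * nFLH / (a_ph(Chl) * iPAR), with a_ph the configured
    chlorophyll-specific absorption power law. Linear in nFLH and
    monotonically decreasing in iPAR. Cells with chlorophyll or iPAR
    below their validity floors (or missing inputs) come back missing —
    never an exception — and their count is reported as a warning.
    """
    cfg = (config or optics_config())["phif"]
    if isinstance(inputs, FluorInputs):
        nflh, ipar, chl = inputs.nflh, inputs.ipar, inputs.chl
    else:
        nflh, ipar, chl = inputs
    wrap_series = isinstance(nflh, pd.Series)
    index = nflh.index if wrap_series else None
    nflh = np.asarray(nflh, dtype=float)
    ipar = np.asarray(ipar, dtype=float)
    chl = np.asarray(chl, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        absorption = cfg["absorption_a"] * chl ** cfg["absorption_e"]
        out = cfg["fluorescence_scale"] * nflh / (absorption * ipar)
    valid = (
        (chl > cfg["chl_floor"]) & (ipar > cfg["ipar_floor"]) & (nflh >= 0)
        & np.isfinite(nflh) & np.isfinite(ipar) & np.isfinite(chl)
    )
    n_masked = int((~valid).sum())
    if n_masked:
        warnings.warn(f"phi_f: {n_masked} cells below validity floors or missing", stacklevel=2)
    out = np.where(valid, out, np.nan)
    if wrap_series:
        return pd.Series(out, index=index, name="phi_f")
    return out


def phi_f_field(nflh: GeoField, ipar: GeoField, chl: GeoField, config: dict | None = None) -> GeoField:
    """Quantum yield on co-registered gridded inputs."""
    for other in (ipar, chl):
        if other.grid != nflh.grid or not other.times.equals(nflh.times):
            raise ValueError("fluorescence inputs are not co-registered")
    values = phi_f((nflh.values, ipar.values, chl.values), config=config)
    return GeoField(grid=nflh.grid, times=nflh.times, values=values, units="", name="phi_f")


def delta_phi_f(phi_series, clim: Climatology):
    """Standardized anomaly of the quantum yield (SD units)."""
    return standardized_anomaly(phi_series, clim)
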