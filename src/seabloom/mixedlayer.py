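"""Mixed-layer depth and temperature from profiles; underwater light.

MLD uses the temperature-difference criterion: the shallowest depth at
which temperature falls 0.2 degC below its value at the 10 m reference
level, located by linear interpolation between the bracketing samples.
Mixed-layer temperature is the mean of good samples above the MLD.

The light chain converts surface chlorophyll to the diffuse attenuation
at 490 nm, then to the broadband Kd(PAR), and averages the exponentially
attenuated irradiance over the mixed layer:

    PAR_ml = PAR_0 (1 - exp(-Kd_PAR * MLD)) / (Kd_PAR * MLD)

All coefficients live in the packaged ``optics.yaml`` configuration.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml

DBAR_TO_M = 1.0e4 / (1025.0 * 9.81)  # hydrostatic, mean seawater density
GOOD_QC = 1
DIAZOTROPH_TEMP_LIMIT = 24.0  # degC, lower edge of the nitrogen-fixer optimum


@lru_cache(maxsize=1)
def optics_config() -> dict:
    text = importlib.resources.files("seabloom.data").joinpath("optics.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class Profile:
    """A vertical temperature profile (depth positive down, metres).

    Construct with ``depth`` or ``pressure`` (dbar); pressure is converted
    with a hydrostatic approximation and the conversion is recorded in
    ``meta``. Only samples with QC flag 1 ("good") enter any computation.
    """

    temperature: np.ndarray
    depth: np.ndarray | None = None
    pressure: np.ndarray | None = None
    qc: np.ndarray | None = None
    float_id: str = ""
    time: pd.Timestamp | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.depth is None:
            if self.pressure is None:
                raise ValueError("provide depth (m) or pressure (dbar)")
            self.depth = np.asarray(self.pressure, dtype=float) * DBAR_TO_M
            self.meta["depth_from_pressure"] = f"z = p * {DBAR_TO_M:.6f} m/dbar (hydrostatic)"
        self.depth = np.asarray(self.depth, dtype=float)
        if self.qc is None:
            self.qc = np.ones(self.depth.size, dtype=int)
        self.qc = np.asarray(self.qc)
        if not (self.depth.size == self.temperature.size == self.qc.size):
            raise ValueError("depth, temperature and qc must have equal length")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depth must be strictly increasing")

    def good(self) -> tuple[np.ndarray, np.ndarray]:
        """(depth, temperature) of good-QC samples only."""
        keep = self.qc == GOOD_QC
        return self.depth[keep], self.temperature[keep]


@dataclass(frozen=True)
class MldResult:
    """MLD estimate in metres; NaN with a flag when the criterion fails."""

    mld: float
    flag: str | None = None


def mld_from_profile(
    profile: Profile,
    delta_t: float = 0.2,
    ref_depth: float = 10.0,
    ref_tolerance: float = 5.0,
) -> MldResult:
    """Temperature-criterion MLD: shallowest depth where T <= T(10 m) - 0.2.

    The reference temperature is the good sample nearest ``ref_depth``
    within ``ref_tolerance`` metres (profiles rarely sample 10 m exactly).
    The crossing depth is linearly interpolated between the bracketing
    samples. An isothermal profile (criterion never met) yields NaN with
    the flag ``"deeper-than-profile"``; a missing reference sample raises.
    """
    depth, temp = profile.good()
    if depth.size == 0:
        raise ValueError("profile has no good-QC samples")
    near = np.abs(depth - ref_depth) <= ref_tolerance
    if not near.any():
        raise ValueError(
            f"no good sample within {ref_tolerance} m of the {ref_depth} m reference"
        )
    i_ref = np.flatnonzero(near)[np.argmin(np.abs(depth[near] - ref_depth))]
    t_ref = temp[i_ref]
    target = t_ref - delta_t
    below = depth > depth[i_ref]
    hits = np.flatnonzero(below & (temp <= target))
    if hits.size == 0:
        return MldResult(mld=np.nan, flag="deeper-than-profile")
    k = hits[0]
    if k == 0 or temp[k - 1] <= target:
        return MldResult(mld=float(depth[k]))
    frac = (temp[k - 1] - target) / (temp[k - 1] - temp[k])
    return MldResult(mld=float(depth[k - 1] + frac * (depth[k] - depth[k - 1])))


def ml_temperature(profile: Profile, mld: float) -> float:
    """Mean of good temperature samples at depth <= mld."""
    depth, temp = profile.good()
    above = depth <= mld
    if not above.any():
        raise ValueError(f"no good samples above the mixed-layer depth ({mld} m)")
    return float(temp[above].mean())


def below_diazotroph_limit(ml_temp: float, limit: float = DIAZOTROPH_TEMP_LIMIT) -> bool:
    """True when the mixed layer is colder than the nitrogen-fixer optimum."""
    return bool(ml_temp < limit)


def kd490_from_chl(chl, config: dict | None = None):
    """Diffuse attenuation at 490 nm (m^-1) from chlorophyll (mg m^-3).

    Pure-water intercept plus a sub-linear power law in chlorophyll; the
    coefficients are configuration (see ``optics.yaml``).
    """
    cfg = (config or optics_config())["kd490"]
    chl_arr = np.asarray(chl, dtype=float)
    if np.any(chl_arr < 0):
        raise ValueError("chlorophyll must be non-negative")
    out = cfg["kw"] + cfg["a"] * chl_arr ** cfg["e"]
    return float(out) if np.isscalar(chl) else out


def kdpar_from_kd490(kd490, config: dict | None = None):
    """Broadband Kd(PAR) (m^-1) from Kd(490) via the configured rational form."""
    cfg = (config or optics_config())["kdpar"]
    kw = (config or optics_config())["kd490"]["kw"]
    kd_arr = np.asarray(kd490, dtype=float)
    if np.any(kd_arr < kw):
        raise ValueError(f"Kd(490) below the pure-water value {kw} m^-1 is non-physical")
    out = cfg["c0"] + cfg["c1"] * kd_arr + cfg["c2"] / kd_arr
    return float(out) if np.isscalar(kd490) else out


def par_in_mixed_layer(par_surface, kd_par, mld):
    """Mean PAR over the mixed layer for exponentially attenuated light.

    PAR_ml = PAR_0 (1 - e^{-Kd z}) / (Kd z) evaluated at z = MLD; the
    limit MLD -> 0 returns the surface value.
    """
    par0 = np.asarray(par_surface, dtype=float)
    kd = np.asarray(kd_par, dtype=float)
    z = np.asarray(mld, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("kd_par must be positive")
    if np.any(z < 0):
        raise ValueError("mld must be non-negative")
    x = kd * z
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(x < 1e-12, 1.0, -np.expm1(-x) / np.where(x == 0, 1.0, x))
    out = par0 * factor
    return float(out) if np.isscalar(par_surface) and np.isscalar(mld) else out
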