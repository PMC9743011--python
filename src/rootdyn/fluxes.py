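"""Closed-form chamber gas flux and hydraulic-conductance corrections.

Static-chamber flux: a chamber of base area A and volume V sits on the
soil while the gas concentration drifts linearly.  The areal flux is

    F_A = dC/dt * (P * M * V) / (R * A * T)      [g m^-2 h^-1]

with dC/dt the fitted concentration slope as a mole-fraction rate
(mol mol^-1 h^-1; ppm = 1e-6 mole fraction), P atmospheric pressure (Pa),
M the molar mass of the gas (g mol^-1), T the chamber temperature (K) and
R = 8.314 J K^-1 mol^-1.  A negative slope means the soil takes the gas up
(a sink) and yields a negative flux.

HPFM temperature correction: measured root hydraulic conductance K_raw is
referred to the calibration temperature via the manufacturer's relation
K_r = K_raw * (0.554 + 0.0225*T) / (0.554 + 0.0225*T_c), temperatures in
degrees Celsius (the linear factor tracks the viscosity change of water).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ChamberGeometry",
    "SlopeFit",
    "fit_slope",
    "gas_flux",
    "HydraulicMeasurement",
    "hpfm_correct",
    "ETHYLENE_CHAMBER",
]

R_GAS = 8.314  # J K^-1 mol^-1


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber geometry and state for the flux equation."""

    area_m2: float
    volume_m3: float
    temperature_k: float
    pressure_pa: float = 101_325.0
    molar_mass_g_mol: float = 28.05  # ethylene C2H4

    def __post_init__(self):
        for name in ("area_m2", "volume_m3", "temperature_k", "pressure_pa", "molar_mass_g_mol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: The study's opaque soil chamber: area 43.4 cm^2, volume 0.634 dm^3.
ETHYLENE_CHAMBER = ChamberGeometry(
    area_m2=43.4e-4, volume_m3=0.634e-3, temperature_k=293.15
)


@dataclass
class SlopeFit:
    slope_molfrac_per_h: float
    slope_ppm_per_h: float
    intercept_ppm: float
    r_squared: float
    stderr_ppm_per_h: float
    n: int


def fit_slope(time_s, concentration_ppm, trim_deadband_s: float = 0.0) -> SlopeFit:
    """OLS slope of chamber concentration against time.

    ``trim_deadband_s`` drops an initial settling window (chamber-placement
    artifact); the default uses the full 6–8-min record.
    """
    t = np.asarray(time_s, dtype=float)
    c = np.asarray(concentration_ppm, dtype=float)
    if trim_deadband_s > 0:
        keep = t >= t[0] + trim_deadband_s
        t, c = t[keep], c[keep]
    if t.size < 3:
        raise ValueError("need at least three time points")
    if np.ptp(t) <= 0:
        raise ValueError("time points must span a positive duration")
    res = stats.linregress(t / 3600.0, c)  # ppm per hour
    return SlopeFit(
        slope_molfrac_per_h=res.slope * 1e-6,
        slope_ppm_per_h=float(res.slope),
        intercept_ppm=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr_ppm_per_h=float(res.stderr),
        n=t.size,
    )


def gas_flux(slope_molfrac_per_h: float, geom: ChamberGeometry) -> float:
    """Signed areal gas flux in g m^-2 h^-1 (negative = sink)."""
    return slope_molfrac_per_h * (
        geom.pressure_pa * geom.molar_mass_g_mol * geom.volume_m3
    ) / (R_GAS * geom.area_m2 * geom.temperature_k)


@dataclass
class HydraulicMeasurement:
    """HPFM reading with its measurement and calibration temperatures (C)."""

    k_raw: float  # g MPa^-1 s^-1
    temperature_c: float
    calibration_temperature_c: float = 22.0
    root_surface_area_cm2: float | None = None


def hpfm_correct(m: HydraulicMeasurement) -> dict:
    """Temperature-corrected conductance K_r and the percent change.

    Returns ``{"k_r": ..., "factor": ..., "percent_change": ...}``;
    ``percent_change`` is negative when the correction reduces K_raw (as
    when measuring in 2 C soil against a 22 C calibration, a ~43%
    decrease).  Optionally ``conductivity`` = K_r / root surface area.
    """
    denom = 0.554 + 0.0225 * m.calibration_temperature_c
    numer = 0.554 + 0.0225 * m.temperature_c
    if denom <= 0 or numer <= 0:
        raise ValueError("correction factor denominators must be positive")
    factor = numer / denom
    k_r = m.k_raw * factor
    out = {"k_r": k_r, "factor": factor, "percent_change": (factor - 1.0) * 100.0}
    if m.root_surface_area_cm2:
        out["conductivity"] = k_r / m.root_surface_area_cm2
    return out
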