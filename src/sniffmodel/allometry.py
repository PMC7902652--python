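"""Allometric scaling of sniffing.

Across mammals, respiratory quantities follow power laws of body mass,
q(M) = a * M**b.  This module houses the published law library (sniff
frequency, tidal and lung volumes, tracheal radius, respiratory compliance
and inertance), ordinary least-squares fitting of new mass--value tables in
log-log space, and four mechanistic predictions of maximum sniff frequency:

f1  inertial     -- lung pressure accelerating the respiratory air column,
f2  resonance    -- natural frequency of the compliance-inertance oscillator,
f3  laminar cap  -- upper bound from the critical Reynolds number, and
f4  infinite-tube Womersley flow-rate balance.

All internal computation is SI; laws carry display units and conversion
happens at the boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AllometricLaw",
    "ScalingModelParams",
    "AnimalRecord",
    "AirwayTransit",
    "PowerLawFit",
    "LAWS",
    "evaluate_law",
    "fit_power_law",
    "combined_vtot_law",
    "f1_inertial",
    "f2_resonance",
    "f3_turbulence_limit",
    "f4_loudon",
    "transit_frequency_limit",
    "lung_to_sniff_ratio",
    "read_animal_table",
    "write_animal_table",
]

ANIMAL_TABLE_COLUMNS = ["species", "mass_kg", "max_sniff_freq_hz", "source"]


@dataclass(frozen=True)
class AllometricLaw:
    """Power law ``value = prefactor * M**exponent`` with M in kg.

    ``prefactor`` is the value of the quantity at M = 1 kg, in
    ``quantity_units``.  ``mass_range`` (kg) marks the span of the data the
    law was fitted on; evaluation outside it warns but proceeds.
    """

    prefactor: float
    exponent: float
    quantity_units: str = ""
    n_samples: int | None = None
    r_squared: float | None = None
    mass_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.prefactor > 0:
            raise ValueError(f"prefactor must be positive, got {self.prefactor}")
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def __call__(self, mass):
        return evaluate_law(self, mass)


@dataclass(frozen=True)
class ScalingModelParams:
    """Physical parameters shared by the mechanistic frequency models.

    ``pressure_convention`` selects the driving pressure used by f1/f4:
    ``"peak"`` uses P_max directly, ``"sinusoidal_mean"`` the mean magnitude
    2*P_max/pi of a sinusoidal waveform.
    """

    max_lung_pressure: float = 10_000.0     # Pa
    pressure_convention: str = "sinusoidal_mean"
    air_density: float = 1.2                # kg m^-3
    air_kinematic_viscosity: float = 1.48e-5  # m^2 s^-1
    critical_reynolds: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("max_lung_pressure", "air_density",
                     "air_kinematic_viscosity", "critical_reynolds"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.pressure_convention not in ("peak", "sinusoidal_mean"):
            raise ValueError(
                f"unknown pressure_convention {self.pressure_convention!r}")

    @property
    def driving_pressure(self) -> float:
        """Driving pressure in Pa under the selected convention."""
        if self.pressure_convention == "peak":
            return self.max_lung_pressure
        return 2.0 * self.max_lung_pressure / math.pi


@dataclass(frozen=True)
class AnimalRecord:
    species: str
    mass: float                 # kg
    max_sniff_frequency: float  # Hz
    source: str = ""

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if not self.max_sniff_frequency > 0:
            raise ValueError(
                f"frequency must be positive, got {self.max_sniff_frequency}")


@dataclass(frozen=True)
class AirwayTransit:
    """Snout length and mean airway speed setting the transit-time limit."""

    snout_length: float  # m
    airway_speed: float  # m s^-1

    def __post_init__(self) -> None:
        if not (self.snout_length > 0 and self.airway_speed > 0):
            raise ValueError("snout_length and airway_speed must be positive")


#: Published law library.  Volumes are in mL, lengths in m, frequencies in Hz,
#: compliance in L/Pa and inertance in Pa L^-1 s^-2 magnitudes.
LAWS: dict[str, AllometricLaw] = {
    "sniff_frequency": AllometricLaw(8.0, -0.18, "Hz", n_samples=16,
                                     r_squared=0.85),
    "sniff_volume": AllometricLaw(2.15, 0.99, "mL", n_samples=7),
    "lung_volume": AllometricLaw(53.5, 1.06, "mL", n_samples=333),
    "vital_capacity": AllometricLaw(56.7, 1.03, "mL", n_samples=315),
    "residual_capacity": AllometricLaw(24.1, 1.13, "mL", n_samples=261),
    "total_volume": AllometricLaw(83.0, 1.06, "mL"),
    "trachea_radius": AllometricLaw(0.0023, 0.4, "m"),
    "breathing_frequency": AllometricLaw(0.89, -0.26, "Hz", n_samples=692),
    "compliance": AllometricLaw(1.59e-5, 1.04, "L/Pa", n_samples=114),
    "inertance": AllometricLaw(7.84, -0.5, "Pa L^-1 s^-2", n_samples=15),
}

_ML_TO_M3 = 1e-6


def evaluate_law(law: AllometricLaw, mass):
    """Evaluate ``law`` at ``mass`` (kg, scalar or array).

    Warns (without failing) when a known ``mass_range`` is exceeded.
    """
    m = np.asarray(mass, dtype=float)
    if np.any(m <= 0):
        raise ValueError(f"mass must be positive, got {mass}")
    if law.mass_range is not None:
        lo, hi = law.mass_range
        if np.any(m < lo) or np.any(m > hi):
            warnings.warn(
                f"mass outside the fitted range [{lo}, {hi}] kg; "
                "extrapolating the power law", stacklevel=2)
    out = law.prefactor * m ** law.exponent
    return float(out) if np.isscalar(mass) or m.ndim == 0 else out


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log OLS fit, with standard errors for inference."""

    law: AllometricLaw
    exponent_se: float
    log10_prefactor_se: float

    @property
    def prefactor(self) -> float:
        return self.law.prefactor

    @property
    def exponent(self) -> float:
        return self.law.exponent

    @property
    def r_squared(self) -> float:
        return self.law.r_squared


def fit_power_law(masses, values, weights=None, units: str = "") -> PowerLawFit:
    """Fit ``value = a * M**b`` by (weighted) OLS on (log10 M, log10 value).

    R^2 is computed in log space, the standard practice in allometry.
    Raises ``ValueError`` naming the first offending index on non-positive
    data.
    """
    m = np.asarray(masses, dtype=float)
    v = np.asarray(values, dtype=float)
    if m.shape != v.shape or m.ndim != 1:
        raise ValueError("masses and values must be 1-d arrays of equal length")
    if len(m) < 3:
        raise ValueError(f"need at least 3 points, got {len(m)}")
    for arr, name in ((m, "mass"), (v, "value")):
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            raise ValueError(
                f"non-positive {name} at index {bad[0]}: {arr[bad[0]]}")

    X = sm.add_constant(np.log10(m))
    y = np.log10(v)
    model = sm.WLS(y, X, weights=weights) if weights is not None else sm.OLS(y, X)
    res = model.fit()
    intercept, slope = res.params
    law = AllometricLaw(
        prefactor=10.0 ** intercept,
        exponent=float(slope),
        quantity_units=units,
        n_samples=len(m),
        r_squared=float(min(res.rsquared, 1.0)),
        mass_range=(float(m.min()), float(m.max())),
    )
    return PowerLawFit(law, exponent_se=float(res.bse[1]),
                       log10_prefactor_se=float(res.bse[0]))


def combined_vtot_law(
    vc: AllometricLaw = LAWS["vital_capacity"],
    vr: AllometricLaw = LAWS["residual_capacity"],
    mass_range: tuple[float, float] = (0.01, 10_000.0),
    n_grid: int = 200,
) -> PowerLawFit:
    """Power-law best fit to the pointwise sum V_c(M) + V_r(M).

    The total respiratory air volume is the sum of vital capacity and
    functional residual capacity; the sum of two power laws is not itself a
    power law, so it is approximated by a fit over a log-spaced mass grid
    spanning the mammalian range (default 0.01--10000 kg, 200 points).
    """
    if vc.quantity_units != vr.quantity_units:
        raise ValueError(
            f"laws must share units, got {vc.quantity_units!r} and "
            f"{vr.quantity_units!r}")
    lo, hi = mass_range
    if not (0 < lo < hi) or n_grid < 3:
        raise ValueError("mass_range must be increasing positive; n_grid >= 3")
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    total = evaluate_law(vc, grid) + evaluate_law(vr, grid)
    return fit_power_law(grid, total, units=vc.quantity_units)


def _model_inputs(mass, params, laws):
    laws = laws or LAWS
    rt = evaluate_law(laws["trachea_radius"], mass)          # m
    vsn = evaluate_law(laws["sniff_volume"], mass) * _ML_TO_M3
    vtot = evaluate_law(laws["total_volume"], mass) * _ML_TO_M3
    return rt, vsn, vtot


def f1_inertial(mass, params: ScalingModelParams = ScalingModelParams(),
                laws: dict | None = None) -> float:
    """Inertial model: lung pressure accelerates the respiratory air column.

    Balancing the applied force P*pi*r_t^2 against the inertia of the total
    air volume displaced sinusoidally by one sniff volume gives
    ``f1 = sqrt(P r_t^4 / (4 rho V_sn V_tot))``.
    """
    rt, vsn, vtot = _model_inputs(mass, params, laws)
    P = params.driving_pressure
    return np.sqrt(P * rt ** 4 / (4.0 * params.air_density * vsn * vtot))


def f2_resonance(mass,
                 compliance_law: AllometricLaw = LAWS["compliance"],
                 inertance_law: AllometricLaw = LAWS["inertance"]) -> float:
    """Resonant frequency 1/(2 pi sqrt(C I)) of the respiratory oscillator.

    C and I enter in their published magnitudes (L/Pa and Pa L^-1 s^-2);
    their product is treated as s^2.
    """
    ci = evaluate_law(compliance_law, mass) * evaluate_law(inertance_law, mass)
    if np.any(np.asarray(ci) <= 0):
        raise ValueError("compliance * inertance must be positive")
    return 1.0 / (2.0 * math.pi * np.sqrt(ci))


def f3_turbulence_limit(mass, params: ScalingModelParams = ScalingModelParams(),
                        laws: dict | None = None) -> float:
    """Upper bound on sniff frequency keeping airway flow laminar.

    From Re_max = 2 U_max r_t / nu with U_max ~ 2 pi f V_sn/(pi r_t^2):
    ``f3 < nu Re_max r_t / (4 V_sn)``.
    """
    rt, vsn, _ = _model_inputs(mass, params, laws)
    return params.air_kinematic_viscosity * params.critical_reynolds * rt / (
        4.0 * vsn)


def f4_loudon(mass, params: ScalingModelParams = ScalingModelParams(),
              laws: dict | None = None) -> float:
    """Infinite-tube oscillatory flow-rate balance: sqrt(P r_t/(rho pi V_tot)).

    Derived by equating the high-Womersley flow-rate amplitude
    Q ~ 2 P r^3/(mu Wo^2) with Q = f V_tot.
    """
    rt, _, vtot = _model_inputs(mass, params, laws)
    P = params.driving_pressure
    return np.sqrt(P * rt / (params.air_density * math.pi * vtot))


def transit_frequency_limit(transit: AirwayTransit) -> tuple[float, float]:
    """(minimum inhalation duration L/U, max frequency 1/(2 L/U)).

    A sniff is only useful if inhaled air reaches the sensory region at the
    rear of the nasal cavity, so the inhale must last at least L/U and the
    full period at least 2 L/U.
    """
    duration = transit.snout_length / transit.airway_speed
    return duration, 1.0 / (2.0 * duration)


def lung_to_sniff_ratio(lung_law: AllometricLaw = LAWS["lung_volume"],
                        sniff_law: AllometricLaw = LAWS["sniff_volume"],
                        mass: float = 1.0) -> float:
    """Ratio of lung volume to sniff tidal volume at a given mass."""
    return evaluate_law(lung_law, mass) / evaluate_law(sniff_law, mass)


def read_animal_table(path) -> list[AnimalRecord]:
    """Read a species/mass/frequency CSV (header required, UTF-8)."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ANIMAL_TABLE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"animal table missing columns: {missing}")
    if "source" not in df.columns:
        df["source"] = ""
    return [
        AnimalRecord(str(r.species), float(r.mass_kg),
                     float(r.max_sniff_freq_hz), str(r.source))
        for r in df.itertuples()
    ]


def write_animal_table(records, path) -> None:
    df = pd.DataFrame(
        [(r.species, r.mass, r.max_sniff_frequency, r.source) for r in records],
        columns=ANIMAL_TABLE_COLUMNS,
    )
    df.to_csv(path, index=False, encoding="utf-8")
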