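"""Quasi-steady diffusive odor deposition on a wall-mounted sensor.

Odorant is advected past the sensor by oscillatory (Womersley) channel flow
and accrues on the sensor only by diffusion; the concentration field itself
carries no time dependence.  At each instant of the sniff cycle the air at
wall distance y moves at speed |u(y, t)| and spends a residence time
``tau = d_s / |u|`` over the sensor of width d_s; a molecule reaches the
wall if its diffusion length ``sqrt(2 D tau)`` exceeds y.  The largest such
y defines the instantaneous capture depth, whose cycle average is the
detected-layer thickness x_eff.  Only this thin near-wall shell contributes
to the signal: the predicted current amplitude is ``A = beta * N_d`` with
N_d the molecule count in the shell and beta a single fitted sensor gain.

Increasing sniff frequency raises the Womersley number, thins the layer and
lowers the per-sniff signal, but delivers more sniffs per second — the
central trade-off this module quantifies via :func:`optimal_frequency`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import constants, integrate, optimize

from .womersley import (AIR, Channel, Fluid, SniffProtocol, velocity_phasor,
                        womersley_number)

__all__ = [
    "OdorSource",
    "DepositionSummary",
    "SniffRegimeLimits",
    "DeviceCalibration",
    "ETHANOL",
    "DEVICE_CHANNEL",
    "DEVICE_CALIBRATION",
    "schmidt_number",
    "headspace_concentration",
    "diffusion_time",
    "capture_depth",
    "detected_layer",
    "molecules_available",
    "predicted_amplitude",
    "fit_beta",
    "deposition_summary",
    "optimal_frequency",
]

#: Schmidt numbers above this mark odorants too sluggish to diffuse to a wall
#: sensor within a transit.
DIFFUSIVE_SC_LIMIT = 4.0


@dataclass(frozen=True)
class OdorSource:
    """Volatile odor source described by Henry's-law equilibrium.

    Defaults describe ethanol/water mixtures: the headspace mole fraction of
    the pure liquid is ``rho_e / (u H P_atm)`` and dilution scales it by the
    liquid volume fraction.
    """

    liquid_volume_fraction: float = 1.0
    liquid_density: float = 789.0       # kg m^-3
    molar_mass: float = 0.04607         # kg mol^-1
    henry_constant: float = 1.9         # mol m^-3 Pa^-1
    ambient_pressure: float = 101_325.0  # Pa
    temperature: float = 298.15         # K

    def __post_init__(self) -> None:
        if not 0.0 <= self.liquid_volume_fraction <= 1.0:
            raise ValueError("liquid_volume_fraction must lie in [0, 1]")
        for name in ("liquid_density", "molar_mass", "henry_constant",
                     "ambient_pressure", "temperature"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


ETHANOL = OdorSource()


@dataclass(frozen=True)
class SniffRegimeLimits:
    """Operating-regime boundaries of the sensing system.

    ``noise_floor``: current amplitude below which the per-cycle signal is
    indistinguishable from sensor noise.  ``slow_sniff_woc``: Wo*C (C in
    parts per thousand) below which the sensor returns to baseline every
    cycle, so sniffing adds nothing over a single inhale.
    """

    noise_floor: float = 0.03      # mA
    slow_sniff_woc: float = 0.01

    def __post_init__(self) -> None:
        if not (self.noise_floor > 0 and self.slow_sniff_woc > 0):
            raise ValueError("limits must be positive")


@dataclass(frozen=True)
class DeviceCalibration:
    """Velocity amplitude of the device at a reference frequency.

    The bellows holds its stroke volume constant across frequencies, so the
    mean-velocity amplitude scales linearly with f:
    ``U_max(f) = u_max_ref * f / f_ref``.  ``u_max_ref`` is a calibration,
    not a prediction: 0.9 m/s is the device-scale amplitude for which the
    first-order capture estimate sqrt(2 D d_s / U) reproduces the measured
    0.35 mm detected layer at the reference operating point (see the methods
    note for why the self-consistent layer comes out thicker).
    """

    u_max_ref: float = 0.9    # m s^-1 at f_ref; calibrated, see docs
    f_ref: float = 0.3        # Hz

    def velocity_amplitude(self, frequency: float) -> float:
        return self.u_max_ref * frequency / self.f_ref

    def protocol(self, frequency: float, **kwargs) -> SniffProtocol:
        return SniffProtocol(frequency=frequency,
                             velocity_amplitude=self.velocity_amplitude(frequency),
                             **kwargs)


#: The bench device's channel: 1 cm radius, 5 mm wide sensor.
DEVICE_CHANNEL = Channel.circular(radius=0.01, length=0.30, sensor_width=0.005)
DEVICE_CALIBRATION = DeviceCalibration()


@dataclass(frozen=True)
class SchmidtResult:
    value: float
    diffusive: bool


def schmidt_number(kinematic_viscosity: float,
                   diffusivity: float) -> SchmidtResult:
    """Sc = nu/D with a diffusive-regime flag (Sc < 4)."""
    if not (kinematic_viscosity > 0 and diffusivity > 0):
        raise ValueError("nu and D must be positive")
    sc = kinematic_viscosity / diffusivity
    return SchmidtResult(sc, sc < DIFFUSIVE_SC_LIMIT)


@dataclass(frozen=True)
class HeadspaceConcentration:
    parts_per_thousand: float
    number_density: float  # molecules m^-3


def headspace_concentration(source: OdorSource) -> HeadspaceConcentration:
    """Headspace concentration from Henry's law.

    Pure-liquid mole fraction ``C = rho_e/(u H P_atm)``, scaled by the liquid
    volume fraction of the mixture; expressed in parts per thousand.  The
    number density follows from the ideal-gas law at the source temperature.
    """
    c_pure = source.liquid_density / (
        source.molar_mass * source.henry_constant * source.ambient_pressure)
    ppt = 1000.0 * c_pure * source.liquid_volume_fraction
    number_density = (ppt / 1000.0) * source.ambient_pressure / (
        constants.k * source.temperature)
    return HeadspaceConcentration(ppt, number_density)


def diffusion_time(distance: float, diffusivity: float) -> float:
    """Time t = x^2/(2 D) to diffuse a distance x."""
    if distance < 0 or diffusivity <= 0:
        raise ValueError("distance must be >= 0 and diffusivity > 0")
    return distance ** 2 / (2.0 * diffusivity)


def capture_depth(time: float, diffusivity: float) -> float:
    """Diffusion length x = sqrt(2 D t); exact inverse of diffusion_time."""
    if time < 0 or diffusivity <= 0:
        raise ValueError("time must be >= 0 and diffusivity > 0")
    return math.sqrt(2.0 * diffusivity * time)


@dataclass(frozen=True)
class DetectedLayer:
    x_eff: float              # m, cycle-averaged capture depth
    times: np.ndarray         # s, phases of the cycle
    per_time_depth: np.ndarray  # m, instantaneous capture depth
    stagnant: bool = False


def detected_layer(channel: Channel, fluid: Fluid, protocol: SniffProtocol,
                   n_time: int = 64) -> DetectedLayer:
    """Detected-layer thickness x_eff of the quasi-steady deposition model.

    The sniff cycle is discretized into ``n_time`` uniform phases.  At phase
    t_k the capture depth is the largest wall distance y satisfying
    ``y <= sqrt(2 D min(d_s/|u(y, t_k)|, 1/(2f)))`` — residence over the
    sensor, capped at half a period because flow reversal sweeps the layer
    away — found by bisection (the bound is monotone near the wall).  x_eff
    is the time average, capped at the channel radius.
    """
    if n_time < 16:
        raise ValueError("n_time must be at least 16")
    D = fluid.diffusivity
    R = channel.radius
    f = protocol.frequency
    t_cycle = np.arange(n_time) / (n_time * f)
    if D == 0.0:
        return DetectedLayer(0.0, t_cycle, np.zeros(n_time))

    u_hat, _, _, _ = velocity_phasor(channel, fluid, protocol)
    omega = 2.0 * math.pi * f
    tau_cap = 1.0 / (2.0 * f)
    x_half_period = capture_depth(tau_cap, D)

    amp = protocol.pressure_amplitude or protocol.velocity_amplitude
    if amp == 0 or np.max(np.abs(u_hat(np.linspace(0, R, 64)))) < 1e-300:
        warnings.warn("stagnant flow: capture limited by half-period "
                      "diffusion only", stacklevel=2)
        return DetectedLayer(min(R, x_half_period), t_cycle,
                             np.full(n_time, min(R, x_half_period)),
                             stagnant=True)

    depths = np.empty(n_time)
    for k, t in enumerate(t_cycle):
        phase = np.exp(1j * omega * t)

        def bound(y):
            speed = abs(np.real(u_hat(R - y) * phase))
            tau = tau_cap if speed == 0 else min(channel.sensor_width / speed,
                                                 tau_cap)
            return capture_depth(tau, D)

        if R <= bound(R):
            depths[k] = R
            continue
        lo, hi = 0.0, R
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mid <= bound(mid):
                lo = mid
            else:
                hi = mid
        depths[k] = 0.5 * (lo + hi)

    x_eff = min(float(np.mean(depths)), R)
    return DetectedLayer(x_eff, t_cycle, depths)


@dataclass(frozen=True)
class MoleculeCount:
    per_sniff: float
    per_second: float
    convention: str = "per_sniff_times_f"


def molecules_available(x_eff: float, channel: Channel,
                        number_density: float, frequency: float,
                        geometry: str = "sensor_footprint") -> MoleculeCount:
    """Molecules within diffusive reach of the sensor.

    Default capture volume is the wall shell of thickness x_eff over the
    sensor footprint d_s x d_s; the per-second count is per-sniff times f.
    """
    if x_eff < 0 or number_density < 0 or frequency <= 0:
        raise ValueError("inputs must be non-negative with frequency > 0")
    if x_eff > channel.radius:
        raise ValueError("x_eff cannot exceed the channel radius")
    if geometry == "sensor_footprint":
        volume = x_eff * channel.sensor_width ** 2
    elif geometry == "wall_annulus":
        # full annular shell of the channel over the sensor's axial extent
        R = channel.radius
        volume = math.pi * (R ** 2 - (R - x_eff) ** 2) * channel.sensor_width
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    per_sniff = number_density * volume
    return MoleculeCount(per_sniff, per_sniff * frequency)


def predicted_amplitude(n_d: float, beta: float) -> float:
    """Predicted current amplitude A = beta * N_d (mA)."""
    if n_d < 0 or beta < 0:
        raise ValueError("N_d and beta must be non-negative")
    return beta * n_d


def fit_beta(observed, model) -> float:
    """Least-squares sensor gain through the origin.

    ``observed`` is a sequence of (Wo, C_ppt, A_mA); ``model(wo, c_ppt)``
    returns the predicted molecule count N_d.  One beta is fitted jointly
    across all observations (all concentrations share a single gain):
    ``beta = sum(A_i N_i) / sum(N_i^2)``.
    """
    obs = list(observed)
    if not obs:
        raise ValueError("need at least one observation")
    a = np.array([o[2] for o in obs], dtype=float)
    if np.any(a < 0):
        raise ValueError("amplitudes must be non-negative")
    n = np.array([model(o[0], o[1]) for o in obs], dtype=float)
    denom = float(np.sum(n * n))
    if denom == 0.0:
        raise ValueError("model predicts zero molecules for all observations")
    return float(np.sum(a * n) / denom)


@dataclass(frozen=True)
class DepositionSummary:
    womersley: float
    concentration_ppt: float
    woc: float
    layer_thickness: float       # m
    molecules_per_sniff: float
    molecules_per_second: float
    predicted_amplitude: float   # mA
    beta: float                  # mA per molecule


def deposition_summary(channel: Channel, fluid: Fluid, source: OdorSource,
                       protocol: SniffProtocol, beta: float,
                       n_time: int = 64) -> DepositionSummary:
    """Run the full deposition chain for one operating point."""
    conc = headspace_concentration(source)
    wo = womersley_number(channel.radius, protocol.frequency,
                          fluid.kinematic_viscosity)
    layer = detected_layer(channel, fluid, protocol, n_time=n_time)
    count = molecules_available(layer.x_eff, channel, conc.number_density,
                                protocol.frequency)
    return DepositionSummary(
        womersley=wo,
        concentration_ppt=conc.parts_per_thousand,
        woc=wo * conc.parts_per_thousand,
        layer_thickness=layer.x_eff,
        molecules_per_sniff=count.per_sniff,
        molecules_per_second=count.per_second,
        predicted_amplitude=predicted_amplitude(count.per_sniff, beta),
        beta=beta,
    )


@dataclass(frozen=True)
class FrequencyRegime:
    frequency: float
    womersley: float
    woc: float
    amplitude: float
    classification: str  # "slow-sniff" | "operational" | "below-noise"


@dataclass(frozen=True)
class OptimalFrequencyReport:
    feasible: bool
    optimal_frequency: float | None
    optimal_womersley: float | None
    regimes: tuple[FrequencyRegime, ...]


def optimal_frequency(channel: Channel, fluid: Fluid, source: OdorSource,
                      beta: float, limits: SniffRegimeLimits,
                      f_grid, calibration: DeviceCalibration = DEVICE_CALIBRATION,
                      n_time: int = 64) -> OptimalFrequencyReport:
    """Fastest feasible sniff: maximize information rate above the noise floor.

    Each grid frequency is classified as ``slow-sniff`` (Wo*C below the
    slow-sniff limit: the signal returns to baseline each cycle),
    ``below-noise`` (predicted amplitude under the noise floor), or
    ``operational``.  The optimum is the largest operational frequency.
    """
    regimes = []
    best = None
    for f in np.asarray(list(f_grid), dtype=float):
        summary = deposition_summary(channel, fluid, source,
                                     calibration.protocol(float(f)), beta,
                                     n_time=n_time)
        if summary.woc < limits.slow_sniff_woc:
            cls = "slow-sniff"
        elif summary.predicted_amplitude < limits.noise_floor:
            cls = "below-noise"
        else:
            cls = "operational"
            if best is None or f > best[0]:
                best = (float(f), summary.womersley)
        regimes.append(FrequencyRegime(float(f), summary.womersley,
                                       summary.woc,
                                       summary.predicted_amplitude, cls))
    if best is None:
        return OptimalFrequencyReport(False, None, None, tuple(regimes))
    return OptimalFrequencyReport(True, best[0], best[1], tuple(regimes))
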