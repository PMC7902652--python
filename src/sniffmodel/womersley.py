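"""Oscillatory (Womersley) laminar flow in a circular channel.

The velocity field of sinusoidally driven flow in a rigid tube is governed by
a single dimensionless group.  Two conventions appear side by side:

* ``Wo = R * sqrt(pi f / (2 nu))`` — the convention used to report device and
  animal operating points (length scale = channel radius = half the hydraulic
  diameter);
* ``alpha = R * sqrt(omega / nu) = 2 * Wo`` with omega = 2 pi f — the
  classical parameter entering the Bessel-function solution.

This module provides the closed-form solution, an independent
finite-difference solver used as a numerical oracle, and small helpers for
hydraulic diameter, bellows kinematics and the Reynolds number.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.special import jv

__all__ = [
    "Fluid",
    "Channel",
    "SniffProtocol",
    "VelocityField",
    "AIR",
    "womersley_number",
    "alpha_parameter",
    "hydraulic_diameter",
    "closed_form_velocity",
    "velocity_phasor",
    "numeric_oscillatory_solver",
    "flow_rate_amplitude",
    "bellows_volume",
    "reynolds_max",
    "velocity_field_to_csv",
]

#: Bessel arguments beyond this magnitude switch to the boundary-layer form.
_BESSEL_OVERFLOW = 600.0


@dataclass(frozen=True)
class Fluid:
    """Carrier fluid with the odorant's mass diffusivity in it."""

    kinematic_viscosity: float  # m^2 s^-1
    density: float              # kg m^-3
    diffusivity: float          # m^2 s^-1

    def __post_init__(self) -> None:
        if not (self.kinematic_viscosity > 0 and self.density > 0
                and self.diffusivity >= 0):
            raise ValueError("fluid properties must be positive")

    @property
    def dynamic_viscosity(self) -> float:
        """mu = rho * nu (Pa s)."""
        return self.density * self.kinematic_viscosity


#: Air at room temperature with ethanol vapor as the odorant.
AIR = Fluid(kinematic_viscosity=1.48e-5, density=1.2, diffusivity=11e-6)


@dataclass(frozen=True)
class Channel:
    """Flow channel reduced to an equivalent circular cross-section.

    Square device channels are mapped to a circle of equal hydraulic
    diameter; the solvers always work on the circular equivalent.
    """

    hydraulic_diameter: float  # m
    length: float              # m
    sensor_width: float        # m
    shape: str = "circle"

    def __post_init__(self) -> None:
        if not (self.hydraulic_diameter > 0 and self.length > 0
                and self.sensor_width > 0):
            raise ValueError("channel dimensions must be positive")
        if self.shape not in ("circle", "square"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not self.sensor_width < self.length:
            raise ValueError("sensor_width must be smaller than channel length")

    @property
    def radius(self) -> float:
        return self.hydraulic_diameter / 2.0

    @property
    def cross_section_area(self) -> float:
        """Area of the circular equivalent (pi R^2); a square of side s has
        D_h = s, and its true area s^2 differs from the equivalent circle's.
        """
        return math.pi * self.radius ** 2

    @classmethod
    def circular(cls, radius: float, length: float, sensor_width: float):
        return cls(2.0 * radius, length, sensor_width, shape="circle")

    @classmethod
    def square(cls, side: float, length: float, sensor_width: float):
        # hydraulic diameter of a square duct equals its side: 4 s^2/(4 s)
        return cls(side, length, sensor_width, shape="square")


@dataclass(frozen=True)
class SniffProtocol:
    """Sinusoidal sniff drive: exactly one of pressure or velocity amplitude.

    ``pressure_amplitude`` is the axial pressure-difference amplitude across
    the channel length (Pa); ``velocity_amplitude`` the amplitude of the
    cross-section-mean velocity (m/s).
    """

    frequency: float                       # Hz
    pressure_amplitude: float | None = None
    velocity_amplitude: float | None = None
    n_cycles: int = 1
    time_resolution: int = 64              # samples per cycle

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")
        if (self.pressure_amplitude is None) == (self.velocity_amplitude is None):
            raise ValueError(
                "exactly one of pressure_amplitude and velocity_amplitude "
                "must be set")
        if self.n_cycles < 1 or self.time_resolution < 4:
            raise ValueError("need n_cycles >= 1 and time_resolution >= 4")


@dataclass
class VelocityField:
    """Axial velocity u(r, t) on a (radius, time) grid."""

    radial_positions: np.ndarray  # m, shape (nr,)
    times: np.ndarray             # s, shape (nt,)
    axial_velocity: np.ndarray    # m/s, shape (nr, nt)
    provenance: str               # "closed_form" | "numerical"
    metadata: dict = field(default_factory=dict)


def womersley_number(length_scale: float, frequency: float,
                     kinematic_viscosity: float) -> float:
    """Wo = l * sqrt(pi f / (2 nu)); call with l = channel radius (= D_h/2)."""
    if length_scale < 0 or frequency < 0 or kinematic_viscosity <= 0:
        raise ValueError("negative inputs not allowed")
    return length_scale * math.sqrt(math.pi * frequency /
                                    (2.0 * kinematic_viscosity))


def alpha_parameter(radius: float, frequency: float,
                    kinematic_viscosity: float) -> float:
    """Classical Womersley parameter alpha = R sqrt(omega/nu) = 2 Wo."""
    return radius * math.sqrt(2.0 * math.pi * frequency / kinematic_viscosity)


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """D_h = 4 A / P for an arbitrary cross-section."""
    if not (area > 0 and perimeter > 0):
        raise ValueError("area and perimeter must be positive")
    return 4.0 * area / perimeter


def _unit_phasor(r_over_R: np.ndarray, alpha: float):
    """Velocity phasor for unit G/(rho omega), i.e. u_hat / (G/(i rho omega)).

    Returns ``1 - J0(i^{3/2} alpha x)/J0(i^{3/2} alpha)`` with the principal
    branch of i^{3/2}; beyond the overflow guard the Stokes boundary-layer
    asymptote ``1 - exp(-(1+i) alpha (1-x)/sqrt(2))`` is used.
    """
    lam = (1j ** 1.5) * alpha
    if abs(lam) > _BESSEL_OVERFLOW:
        return 1.0 - np.exp(-(1.0 + 1j) * alpha * (1.0 - r_over_R) /
                            math.sqrt(2.0)), True
    return 1.0 - jv(0, lam * r_over_R) / jv(0, lam), False


def _mean_unit_phasor(alpha: float) -> complex:
    """Cross-section average of the unit phasor: 1 - 2 J1(L)/(L J0(L))."""
    lam = (1j ** 1.5) * alpha
    if abs(lam) > _BESSEL_OVERFLOW:
        # boundary-layer average: 1 - sqrt(2)(1-i)/alpha + O(alpha^-2)
        return 1.0 - math.sqrt(2.0) * (1.0 - 1j) / alpha
    return 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))


def velocity_phasor(channel: Channel, fluid: Fluid, protocol: SniffProtocol):
    """Return (u_hat(r) callable, pressure-gradient amplitude G, alpha).

    The physical field is ``u(r, t) = Re{u_hat(r) e^{i omega t}}`` for the
    momentum balance ``du/dt = (G/rho) cos(omega t) + nu Laplacian(u)``.
    For a velocity-driven protocol, G is back-solved so the amplitude of the
    cross-section-mean velocity equals ``velocity_amplitude``.
    """
    R = channel.radius
    omega = 2.0 * math.pi * protocol.frequency
    alpha = alpha_parameter(R, protocol.frequency, fluid.kinematic_viscosity)

    if protocol.pressure_amplitude is not None:
        G = protocol.pressure_amplitude / channel.length
    else:
        mean_mag = abs(_mean_unit_phasor(alpha)) / (fluid.density * omega)
        G = protocol.velocity_amplitude / mean_mag

    scale = G / (1j * fluid.density * omega)

    def u_hat(r):
        shape, asymptotic = _unit_phasor(np.asarray(r, dtype=float) / R, alpha)
        return scale * shape

    _, asymptotic = _unit_phasor(np.array([0.0]), alpha)
    return u_hat, G, alpha, asymptotic


def closed_form_velocity(channel: Channel, fluid: Fluid,
                         protocol: SniffProtocol,
                         n_radial: int = 101) -> VelocityField:
    """Closed-form oscillatory velocity field in the circular channel.

    ``u(r,t) = Re{ (G/(i rho omega)) [1 - J0(i^{3/2} a r/R)/J0(i^{3/2} a)]
    e^{i omega t} }``.  Satisfies no-slip at r = R exactly and is periodic
    with period 1/f.
    """
    if channel.shape == "square":
        channel = Channel.circular(channel.radius, channel.length,
                                   channel.sensor_width)
    u_hat, G, alpha, asymptotic = velocity_phasor(channel, fluid, protocol)
    r = np.linspace(0.0, channel.radius, n_radial)
    nt = protocol.n_cycles * protocol.time_resolution
    t = np.arange(nt) / (protocol.time_resolution * protocol.frequency)
    omega = 2.0 * math.pi * protocol.frequency
    field = np.real(u_hat(r)[:, None] * np.exp(1j * omega * t)[None, :])
    return VelocityField(
        r, t, field, "closed_form",
        metadata={
            "alpha": alpha,
            "womersley": alpha / 2.0,
            "frequency_hz": protocol.frequency,
            "pressure_gradient_amplitude": G,
            "asymptotic_boundary_layer": bool(asymptotic),
        },
    )


def numeric_oscillatory_solver(channel: Channel, fluid: Fluid,
                               protocol: SniffProtocol,
                               n_radial: int = 201,
                               steps_per_period: int = 256,
                               tol: float = 1e-8,
                               max_periods: int = 50) -> VelocityField:
    """Finite-difference oracle for the oscillatory channel flow.

    Integrates ``du/dt = (G/rho) cos(omega t) + nu (1/r) d/dr (r du/dr)``
    by Crank-Nicolson on a uniform radial grid (no-slip at R, symmetry at 0)
    from rest until the periodic steady state: successive periods must agree
    to ``tol`` in relative L2 norm.  Intended as an independent check of
    :func:`closed_form_velocity`.
    """
    if channel.shape == "square":
        channel = Channel.circular(channel.radius, channel.length,
                                   channel.sensor_width)
    R = channel.radius
    nu = fluid.kinematic_viscosity
    omega = 2.0 * math.pi * protocol.frequency
    alpha = alpha_parameter(R, protocol.frequency, nu)

    if protocol.pressure_amplitude is not None:
        G = protocol.pressure_amplitude / channel.length
    else:
        # amplitude back-solved analytically; the field itself is still
        # produced by the finite-difference integration
        G = velocity_phasor(channel, fluid, protocol)[1]

    n = n_radial
    r = np.linspace(0.0, R, n)
    dr = r[1] - r[0]
    dt = 1.0 / (protocol.frequency * steps_per_period)

    # Laplacian in cylindrical radial coordinates; interior rows i = 1..n-2
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    for i in range(1, n - 1):
        main[i] = -2.0 / dr ** 2
        lower[i - 1] = 1.0 / dr ** 2 - 1.0 / (2.0 * r[i] * dr)
        upper[i] = 1.0 / dr ** 2 + 1.0 / (2.0 * r[i] * dr)
    # r = 0: symmetry, (1/r)(r u')' -> 2 u'' with u'(0)=0 -> 4(u1-u0)/dr^2
    main[0] = -4.0 / dr ** 2
    upper[0] = 4.0 / dr ** 2
    # r = R: Dirichlet no-slip
    main[-1] = 0.0
    lower[-1] = 0.0
    L = sparse.diags([lower, main, upper], [-1, 0, 1], format="csc") * nu

    I = sparse.identity(n, format="csc")
    A = (I - 0.5 * dt * L).tocsc()
    B = (I + 0.5 * dt * L).tocsc()
    # keep the wall row exactly Dirichlet
    A = A.tolil(); A[-1, :] = 0.0; A[-1, -1] = 1.0; A = A.tocsc()
    B = B.tolil(); B[-1, :] = 0.0; B[-1, -1] = 0.0; B = B.tocsc()
    solve = splu(A).solve

    u = np.zeros(n)
    forcing = np.zeros(n)
    prev_period = None
    snapshots = np.empty((n, steps_per_period))
    for period in range(max_periods):
        for k in range(steps_per_period):
            t_mid = (period * steps_per_period + k + 0.5) * dt
            forcing[:] = (G / fluid.density) * math.cos(omega * t_mid)
            forcing[-1] = 0.0
            u = solve(B @ u + dt * forcing)
            snapshots[:, k] = u
        if prev_period is not None:
            denom = np.linalg.norm(prev_period)
            resid = (np.linalg.norm(snapshots - prev_period) /
                     denom if denom > 0 else 0.0)
            if resid < tol:
                break
        prev_period = snapshots.copy()
    else:
        raise RuntimeError(
            f"oscillatory solver did not reach a periodic state in "
            f"{max_periods} periods (last residual {resid:.3e})")

    # resample this converged period onto the requested time resolution
    stride = max(1, steps_per_period // protocol.time_resolution)
    idx = np.arange(0, steps_per_period, stride)
    # snapshot k holds u at t = (k+1) dt of the period; shift so t starts at 0
    times = ((idx + 1) * dt) % (1.0 / protocol.frequency)
    order = np.argsort(times)
    return VelocityField(
        r, times[order], snapshots[:, idx][:, order], "numerical",
        metadata={
            "alpha": alpha,
            "womersley": alpha / 2.0,
            "frequency_hz": protocol.frequency,
            "pressure_gradient_amplitude": G,
            "periods_to_converge": period + 1,
            "residual": resid,
        },
    )


def flow_rate_amplitude(pressure: float, radius: float,
                        dynamic_viscosity: float, womersley: float) -> float:
    """High-Wo flow-rate amplitude ``Q ~ 2 P r^3 / (mu Wo^2)`` (m^3/s)."""
    if womersley == 0:
        raise ValueError("womersley must be non-zero")
    if pressure < 0 or radius <= 0 or dynamic_viscosity <= 0:
        raise ValueError("inputs must be positive")
    return 2.0 * pressure * radius ** 3 / (dynamic_viscosity * womersley ** 2)


def bellows_volume(velocity_amplitude: float, tube_area: float,
                   frequency: float) -> float:
    """Bellows stroke volume delta V_b = U_max A_t / f (conservation of mass)."""
    if frequency == 0:
        raise ValueError("frequency must be non-zero")
    if velocity_amplitude < 0 or tube_area <= 0 or frequency < 0:
        raise ValueError("inputs must be positive")
    return velocity_amplitude * tube_area / frequency


def reynolds_max(velocity_amplitude: float, radius: float,
                 kinematic_viscosity: float,
                 critical: float = 2000.0) -> tuple[float, bool]:
    """(Re_max = 2 U_max r / nu, laminar flag Re_max < critical)."""
    if velocity_amplitude < 0 or radius <= 0 or kinematic_viscosity <= 0:
        raise ValueError("inputs must be positive")
    re = 2.0 * velocity_amplitude * radius / kinematic_viscosity
    return re, re < critical


def velocity_field_to_csv(field: VelocityField, path) -> None:
    """Long-format CSV (r_m, t_s, u_m_per_s) plus a JSON metadata sidecar."""
    r, t = np.meshgrid(field.radial_positions, field.times, indexing="ij")
    pd.DataFrame({
        "r_m": r.ravel(),
        "t_s": t.ravel(),
        "u_m_per_s": field.axial_velocity.ravel(),
    }).to_csv(path, index=False)
    sidecar = {"provenance": field.provenance, **{
        k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
        for k, v in field.metadata.items()}}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
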