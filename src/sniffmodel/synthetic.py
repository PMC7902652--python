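"""Seeded synthetic-data generators.

Every stage of the analysis is testable without downloads: generators here
produce sensor-current traces with the structure of real device recordings
(baseline, first-order odor response, sniff-synchronized ripple,
non-negative noise), allometric mass--frequency tables drawn from a known
power law with log-normal scatter, and audio-envelope-like sniff pulse
trains.  All generators are pure functions of their spec (including the
seed) and return their ground truth alongside the data, so downstream tests
are closed-loop: generate, analyze, compare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np

from .allometry import AnimalRecord
from .trace import SensorTrace

__all__ = [
    "TraceGenSpec",
    "AllometryGenSpec",
    "EnvelopeGenSpec",
    "gen_sensor_trace",
    "gen_allometry",
    "gen_envelope",
]


@dataclass(frozen=True)
class TraceGenSpec:
    """Sensor-trace generator parameters.

    Defaults emulate the bench device's ethanol recordings: 10 mA baseline
    rising to 20 mA while odor is present (windows in seconds), a sinusoidal
    ripple of half-range ``cycle_amplitude`` synchronized with sniffing, a
    first-order sensor lag, and zero-mean noise clipped so current stays
    non-negative.
    """

    baseline: float = 10.0             # mA
    response_magnitude: float = 10.0   # mA
    sniff_frequency: float = 0.3       # Hz
    cycle_amplitude: float = 0.5       # mA, half peak-to-trough
    sensor_time_constant: float = 5.0  # s
    noise_sd: float = 0.05             # mA
    noise_model: str = "gaussian_clipped_at_zero"
    odor_windows: tuple[tuple[float, float], ...] = ((30.0, 90.0),)
    duration: float = 120.0            # s
    sample_rate: float = 20.0          # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline", "response_magnitude", "cycle_amplitude",
                     "sensor_time_constant", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_model not in ("gaussian_clipped_at_zero", "lognormal"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if not self.sniff_frequency > 0 or not self.sample_rate > 0:
            raise ValueError("frequencies must be positive")
        for a, b in self.odor_windows:
            if not (0 <= a < b <= self.duration):
                raise ValueError("duration must cover all odor windows")


@dataclass(frozen=True)
class AllometryGenSpec:
    """Mass--frequency table from a known power law with log-normal scatter.

    Defaults emulate the structure of the observed mammal dataset: n = 16
    animals log-uniform from shrew to elephant scale, f = 8 M^-0.18 Hz, and
    a base-10 log scatter of 0.11 (chosen by simulation so the fitted R^2
    is ~0.85 on average).
    """

    true_prefactor: float = 8.0
    true_exponent: float = -0.18
    n_points: int = 16
    mass_range: tuple[float, float] = (0.02, 3400.0)
    log_scatter_sd: float = 0.11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        lo, hi = self.mass_range
        if not (0 < lo < hi):
            raise ValueError("mass_range must be positive and increasing")
        if self.true_prefactor <= 0 or self.log_scatter_sd < 0:
            raise ValueError("prefactor must be positive, scatter >= 0")


@dataclass(frozen=True)
class EnvelopeGenSpec:
    """Audio-envelope pulse train at a known repetition rate."""

    pulse_rate: float = 8.0    # Hz
    duration: float = 4.0      # s
    sample_rate: float = 200.0  # Hz
    snr: float = math.inf      # peak amplitude / noise sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate < 10.0 * self.pulse_rate:
            raise ValueError("sample_rate must be >= 10x pulse_rate")
        if self.duration <= 0 or self.pulse_rate <= 0 or self.snr <= 0:
            raise ValueError("duration, pulse_rate and snr must be positive")


def _first_order_level(t: np.ndarray, spec: TraceGenSpec) -> np.ndarray:
    """Odor level following a first-order lag toward the window target."""
    target = np.zeros_like(t)
    for a, b in spec.odor_windows:
        target[(t >= a) & (t < b)] = 1.0
    if spec.sensor_time_constant == 0.0:
        return target
    dt = 1.0 / spec.sample_rate
    decay = math.exp(-dt / spec.sensor_time_constant)
    level = np.empty_like(t)
    prev = 0.0
    for i, tgt in enumerate(target):
        prev = tgt + (prev - tgt) * decay
        level[i] = prev
    return level


def gen_sensor_trace(spec: TraceGenSpec) -> tuple[SensorTrace, dict]:
    """Generate a sensor trace; returns (trace, ground-truth dict)."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate

    level = _first_order_level(t, spec)
    current = spec.baseline + spec.response_magnitude * level

    ripple = np.zeros_like(t)
    for a, b in spec.odor_windows:
        sel = (t >= a) & (t < b)
        ripple[sel] = spec.cycle_amplitude * np.sin(
            2.0 * math.pi * spec.sniff_frequency * (t[sel] - a))
    current = current + ripple

    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian_clipped_at_zero":
            noise = rng.normal(0.0, spec.noise_sd, n)
        else:
            # log-normal shape scaled to the requested sd, shifted to zero mean
            sigma = 0.5
            raw = rng.lognormal(0.0, sigma, n)
            raw_sd = math.sqrt(
                (math.exp(sigma ** 2) - 1.0) * math.exp(sigma ** 2))
            noise = (raw - math.exp(sigma ** 2 / 2.0)) * spec.noise_sd / raw_sd
        current = current + noise
    current = np.clip(current, 0.0, None)

    trace = SensorTrace(t, current, spec.sample_rate, spec.odor_windows)
    return trace, asdict(spec)


def gen_allometry(spec: AllometryGenSpec) -> tuple[list[AnimalRecord], dict]:
    """Generate synthetic animal records; returns (records, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.mass_range
    log_m = rng.uniform(math.log10(lo), math.log10(hi), spec.n_points)
    eps = rng.normal(0.0, spec.log_scatter_sd, spec.n_points)
    masses = 10.0 ** log_m
    freqs = spec.true_prefactor * masses ** spec.true_exponent * 10.0 ** eps
    records = [
        AnimalRecord(f"synthetic-{i:02d}", float(m), float(f), "synthetic")
        for i, (m, f) in enumerate(zip(masses, freqs))
    ]
    return records, asdict(spec)


def gen_envelope(spec: EnvelopeGenSpec) -> tuple[np.ndarray, dict]:
    """Raised-cosine pulse train plus noise at the stated SNR."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    # periodic raised-cosine bumps peaking once per pulse period
    envelope = (0.5 * (1.0 + np.cos(2.0 * math.pi * spec.pulse_rate * t))) ** 4
    if math.isfinite(spec.snr):
        envelope = envelope + rng.normal(0.0, 1.0 / spec.snr, n)
    return envelope, asdict(spec)
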