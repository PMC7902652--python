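"""Orchestration: validated run configs and end-to-end reproduction runs.

Two reproductions mirror the study's headline analyses:

* :func:`reproduce_scaling` — fit the empirical sniff-frequency power law to
  an animal table and tabulate the four mechanistic model curves plus the
  relaxed-breathing line over a mass grid;
* :func:`reproduce_tradeoff` — sweep sniffing frequency for the bench
  device, producing amplitude-vs-Wo*C curves for the three ethanol
  concentrations, per-sniff and per-second molecule counts, regime
  boundaries and the optimal frequency per concentration.

Outputs are CSV + JSON only; every run writes a manifest (config hash,
seed, package version) so deterministic stages reproduce bitwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .allometry import (LAWS, ScalingModelParams, evaluate_law, f1_inertial,
                        f2_resonance, f3_turbulence_limit, f4_loudon,
                        fit_power_law, read_animal_table)
from .deposition import (DeviceCalibration, OdorSource, SniffRegimeLimits,
                         deposition_summary, headspace_concentration,
                         molecules_available, detected_layer,
                         optimal_frequency)
from .womersley import AIR, Channel, Fluid

logger = logging.getLogger("sniffmodel")

__all__ = ["RunConfig", "load_config", "reproduce_scaling",
           "reproduce_tradeoff", "write_manifest"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChannelConfig(_StrictModel):
    radius_m: float = 0.01
    length_m: float = 0.30
    sensor_width_m: float = 0.005


class FluidConfig(_StrictModel):
    nu: float = 1.48e-5
    rho: float = 1.2
    diffusivity: float = 11e-6


class SourceConfig(_StrictModel):
    fraction: float = 1.0
    rho_e: float = 789.0
    molar_mass: float = 0.04607
    henry: float = 1.9
    p_atm: float = 101_325.0
    temp: float = 298.15


class LimitsConfig(_StrictModel):
    noise_floor_mA: float = 0.03
    slow_sniff_woc: float = 0.01


class CalibrationConfig(_StrictModel):
    u_max: float = 0.9
    f_ref: float = 0.3


class ScalingConfig(_StrictModel):
    mass_range_kg: tuple[float, float] = (0.01, 10_000.0)
    n_grid: int = 200
    pressure_convention: str = "sinusoidal_mean"


class TradeoffConfig(_StrictModel):
    frequencies_hz: list[float] = Field(
        default_factory=lambda: list(np.round(np.arange(0.05, 1.01, 0.05), 3)))
    fractions: list[float] = Field(default_factory=lambda: [0.1, 0.5, 1.0])
    beta: float | None = None        # fitted/calibrated if absent
    n_time: int = 64


class RunConfig(_StrictModel):
    """Full run configuration; unknown keys are rejected."""

    channel: ChannelConfig = ChannelConfig()
    fluid: FluidConfig = FluidConfig()
    source: SourceConfig = SourceConfig()
    limits: LimitsConfig = LimitsConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    scaling: ScalingConfig = ScalingConfig()
    tradeoff: TradeoffConfig = TradeoffConfig()
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def build_channel(self) -> Channel:
        return Channel.circular(self.channel.radius_m, self.channel.length_m,
                                self.channel.sensor_width_m)

    def build_fluid(self) -> Fluid:
        return Fluid(self.fluid.nu, self.fluid.rho, self.fluid.diffusivity)

    def build_source(self, fraction: float | None = None) -> OdorSource:
        return OdorSource(
            liquid_volume_fraction=(self.source.fraction
                                    if fraction is None else fraction),
            liquid_density=self.source.rho_e,
            molar_mass=self.source.molar_mass,
            henry_constant=self.source.henry,
            ambient_pressure=self.source.p_atm,
            temperature=self.source.temp,
        )

    def build_limits(self) -> SniffRegimeLimits:
        return SniffRegimeLimits(self.limits.noise_floor_mA,
                                 self.limits.slow_sniff_woc)

    def build_calibration(self) -> DeviceCalibration:
        return DeviceCalibration(self.calibration.u_max, self.calibration.f_ref)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config (schema-checked, strict keys)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def write_manifest(config: RunConfig, out_dir: Path) -> dict:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def reproduce_scaling(config: RunConfig, animals_csv,
                      out_dir=None) -> dict:
    """Empirical fit plus the four model curves and the breathing line.

    Reads the animal table, fits the sniff-frequency power law in log-log
    space, evaluates f1--f4 and the relaxed-breathing law over the
    configured mass grid, writes ``scaling_curves.csv`` and
    ``scaling_report.json`` and returns the report dict.
    """
    animals_csv = Path(animals_csv)
    if not animals_csv.exists():
        raise FileNotFoundError(f"animal table not found: {animals_csv}")
    out_dir = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = read_animal_table(animals_csv)
    fit = fit_power_law([r.mass for r in records],
                        [r.max_sniff_frequency for r in records], units="Hz")
    logger.info("empirical fit: f = %.3g M^%.3g (R^2 = %.3f, n = %d)",
                fit.prefactor, fit.exponent, fit.r_squared, len(records))

    params = ScalingModelParams(
        pressure_convention=config.scaling.pressure_convention)
    lo, hi = config.scaling.mass_range_kg
    grid = np.logspace(np.log10(lo), np.log10(hi), config.scaling.n_grid)
    curves = pd.DataFrame({
        "mass_kg": grid,
        "empirical_fit_hz": fit.law(grid),
        "f1_inertial_hz": f1_inertial(grid, params),
        "f2_resonance_hz": f2_resonance(grid),
        "f3_laminar_limit_hz": f3_turbulence_limit(grid, params),
        "f4_infinite_tube_hz": f4_loudon(grid, params),
        "breathing_hz": evaluate_law(LAWS["breathing_frequency"], grid),
    })
    curves.to_csv(out_dir / "scaling_curves.csv", index=False)

    report = {
        "n_animals": len(records),
        "empirical": {"prefactor_hz": fit.prefactor,
                      "exponent": fit.exponent,
                      "r_squared": fit.r_squared,
                      "exponent_se": fit.exponent_se},
        "models": {
            "f1_inertial": {"value_at_1kg_hz": float(f1_inertial(1.0, params)),
                            "exponent": -0.225},
            "f2_resonance": {"value_at_1kg_hz": float(f2_resonance(1.0)),
                             "exponent": -0.27},
            "f3_laminar_limit": {
                "value_at_1kg_hz": float(f3_turbulence_limit(1.0, params)),
                "exponent": -0.59},
            "f4_infinite_tube": {
                "value_at_1kg_hz": float(f4_loudon(1.0, params)),
                "exponent": -0.33},
            "breathing": {"value_at_1kg_hz": 0.89, "exponent": -0.26},
        },
        "mass_range_kg": [lo, hi],
    }
    with open(out_dir / "scaling_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    write_manifest(config, out_dir)
    return report


def calibrate_beta(config: RunConfig) -> float:
    """Sensor gain such that the lowest concentration sits exactly at the
    noise floor at the reference frequency — the device's measured limit."""
    channel = config.build_channel()
    fluid = config.build_fluid()
    cal = config.build_calibration()
    source = config.build_source(fraction=min(config.tradeoff.fractions))
    n = headspace_concentration(source).number_density
    layer = detected_layer(channel, fluid, cal.protocol(cal.f_ref),
                           n_time=config.tradeoff.n_time)
    nd = molecules_available(layer.x_eff, channel, n, cal.f_ref).per_sniff
    return config.limits.noise_floor_mA / nd


def reproduce_tradeoff(config: RunConfig, out_dir=None) -> dict:
    """Amplitude and molecule-count curves over the sniff-frequency sweep.

    For every configured concentration and frequency, runs the deposition
    chain and writes ``tradeoff_curves.csv`` (wo, freq_hz, c_ppt, woc,
    x_eff_m, nd_per_sniff, nd_per_s, amp_mA, classification) plus a JSON
    report with the regime boundaries and optimal frequency per
    concentration.  An infeasible regime set is reported, not raised.
    """
    out_dir = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channel = config.build_channel()
    fluid = config.build_fluid()
    limits = config.build_limits()
    cal = config.build_calibration()
    beta = config.tradeoff.beta
    if beta is None:
        beta = calibrate_beta(config)
        logger.info("calibrated beta = %.3e mA/molecule", beta)

    rows = []
    optima = {}
    for fraction in config.tradeoff.fractions:
        source = config.build_source(fraction=fraction)
        report = optimal_frequency(channel, fluid, source, beta, limits,
                                   config.tradeoff.frequencies_hz,
                                   calibration=cal,
                                   n_time=config.tradeoff.n_time)
        c_ppt = headspace_concentration(source).parts_per_thousand
        n_dens = headspace_concentration(source).number_density
        for regime in report.regimes:
            layer = detected_layer(channel, fluid,
                                   cal.protocol(regime.frequency),
                                   n_time=config.tradeoff.n_time)
            count = molecules_available(layer.x_eff, channel, n_dens,
                                        regime.frequency)
            rows.append({
                "wo": regime.womersley,
                "freq_hz": regime.frequency,
                "c_ppt": c_ppt,
                "woc": regime.woc,
                "x_eff_m": layer.x_eff,
                "nd_per_sniff": count.per_sniff,
                "nd_per_s": count.per_second,
                "amp_mA": regime.amplitude,
                "classification": regime.classification,
            })
        optima[f"{c_ppt:.1f}_ppt"] = {
            "feasible": report.feasible,
            "optimal_frequency_hz": report.optimal_frequency,
            "optimal_womersley": report.optimal_womersley,
        }
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "tradeoff_curves.csv", index=False)

    report = {
        "beta_mA_per_molecule": beta,
        "noise_floor_mA": limits.noise_floor,
        "slow_sniff_woc": limits.slow_sniff_woc,
        "optima": optima,
    }
    with open(out_dir / "tradeoff_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    write_manifest(config, out_dir)
    return report
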