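"""Quasi-steady deposition model: capture depth, molecule counts, trade-off."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sniffmodel.deposition import (DEVICE_CALIBRATION, DEVICE_CHANNEL,
                                   DeviceCalibration, OdorSource,
                                   SniffRegimeLimits, capture_depth,
                                   deposition_summary, detected_layer,
                                   diffusion_time, fit_beta,
                                   headspace_concentration,
                                   molecules_available, optimal_frequency,
                                   predicted_amplitude, schmidt_number)
from sniffmodel.womersley import (AIR, Fluid, SniffProtocol, velocity_phasor,
                                  womersley_number)


class TestSchmidt:
    def test_ethanol_in_air_is_diffusive(self):
        sc = schmidt_number(1.48e-5, 11e-6)
        assert sc.value == pytest.approx(1.35, abs=0.01)
        assert sc.diffusive

    def test_equal_diffusivities_give_unity(self):
        assert schmidt_number(1e-5, 1e-5).value == 1.0

    def test_threshold_at_four(self):
        assert not schmidt_number(5e-5, 1e-5).diffusive
        assert schmidt_number(3.9e-5, 1e-5).diffusive


class TestHeadspace:
    def test_pure_ethanol_is_89_parts_per_thousand(self):
        c = headspace_concentration(OdorSource())
        assert c.parts_per_thousand == pytest.approx(89.0, abs=0.5)

    def test_half_dilution_is_44(self):
        c = headspace_concentration(OdorSource(liquid_volume_fraction=0.5))
        assert c.parts_per_thousand == pytest.approx(44.5, abs=0.5)

    def test_zero_fraction_gives_zero(self):
        c = headspace_concentration(OdorSource(liquid_volume_fraction=0.0))
        assert c.parts_per_thousand == 0.0
        assert c.number_density == 0.0

    def test_number_density_matches_ideal_gas(self):
        c = headspace_concentration(OdorSource())
        expected = (c.parts_per_thousand / 1000.0) * 101325.0 / \
            (1.380649e-23 * 298.15)
        assert c.number_density == pytest.approx(expected, rel=1e-9)


class TestDiffusionKinetics:
    @pytest.mark.parametrize("D,expected", [(8.2e-10, 0.061),
                                            (6.5e-10, 0.077)])
    def test_mucus_travel_time(self, D, expected):
        # 10-um mucus layer: travel time 0.06-0.08 s
        assert diffusion_time(10e-6, D) == pytest.approx(expected, abs=0.001)

    def test_zero_distance_zero_time(self):
        assert diffusion_time(0.0, 1e-9) == 0.0
        assert capture_depth(0.0, 1e-9) == 0.0

    def test_sensor_transit_capture_depth(self):
        # residence 5 mm / 0.9 m/s in air gives the ~0.35 mm detected scale
        tau = 0.005 / 0.9
        assert capture_depth(tau, 11e-6) == pytest.approx(3.5e-4, rel=0.01)

    @given(st.floats(1e-7, 1e-2), st.floats(1e-10, 1e-4))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_exact(self, x, D):
        assert capture_depth(diffusion_time(x, D), D) == pytest.approx(
            x, rel=1e-12)


class TestDetectedLayer:
    def test_no_diffusion_no_capture(self, device_channel, device_protocol):
        dry = Fluid(1.48e-5, 1.2, 0.0)
        assert detected_layer(device_channel, dry, device_protocol).x_eff == 0.0

    def test_operating_point_layer_is_submillimetre(self, device_channel, air,
                                                     device_protocol):
        layer = detected_layer(device_channel, air, device_protocol)
        # thin layer: well under a tenth of the radius at the device's
        # operating point, same order as the first-order 0.35 mm estimate
        assert 1e-4 < layer.x_eff < 1.2e-3
        assert np.all(layer.per_time_depth <= device_channel.radius + 1e-15)

    def test_layer_thins_as_velocity_grows(self, device_channel, air):
        xs = [detected_layer(device_channel, air,
                             SniffProtocol(frequency=0.3,
                                           velocity_amplitude=u),
                             n_time=32).x_eff
              for u in (0.3, 0.6, 0.9, 1.8, 3.6)]
        assert all(a > b for a, b in zip(xs, xs[1:]))

    def test_stagnant_flow_caps_at_half_period_depth(self, device_channel,
                                                     air):
        prot = SniffProtocol(frequency=0.3, pressure_amplitude=0.0)
        with pytest.warns(UserWarning, match="stagnant"):
            layer = detected_layer(device_channel, air, prot)
        assert layer.stagnant
        assert layer.x_eff == pytest.approx(
            min(device_channel.radius, math.sqrt(2 * 11e-6 / 0.6)), rel=1e-12)


class TestMoleculeCounts:
    def test_zero_density_zero_molecules(self, device_channel):
        count = molecules_available(1e-4, device_channel, 0.0, 0.3)
        assert count.per_sniff == 0.0 and count.per_second == 0.0

    def test_per_second_is_per_sniff_times_frequency(self, device_channel):
        count = molecules_available(1e-4, device_channel, 1e20, 0.3)
        assert count.per_second == pytest.approx(count.per_sniff * 0.3,
                                                 rel=1e-12)

    def test_rejects_layer_thicker_than_radius(self, device_channel):
        with pytest.raises(ValueError, match="radius"):
            molecules_available(0.02, device_channel, 1e20, 0.3)

    def test_molecule_count_shapes_over_wo_sweep(self, device_channel, air):
        # per-sniff molecules fall with Wo, per-second molecules rise
        source = OdorSource(liquid_volume_fraction=0.1)
        dens = headspace_concentration(source).number_density
        wos = np.linspace(0.5, 7.5, 10)
        freqs = (wos / device_channel.radius) ** 2 * \
            2 * air.kinematic_viscosity / math.pi
        per_sniff, per_second = [], []
        for f in freqs:
            layer = detected_layer(device_channel, air,
                                   DEVICE_CALIBRATION.protocol(float(f)),
                                   n_time=32)
            c = molecules_available(layer.x_eff, device_channel, dens,
                                    float(f))
            per_sniff.append(c.per_sniff)
            per_second.append(c.per_second)
        assert all(a > b for a, b in zip(per_sniff, per_sniff[1:]))
        assert all(a < b for a, b in zip(per_second, per_second[1:]))

    def test_conservation_bound(self, device_channel, air, device_protocol):
        # captured molecules cannot exceed what is advected past the sensor
        source = OdorSource()
        dens = headspace_concentration(source).number_density
        layer = detected_layer(device_channel, air, device_protocol)
        captured = molecules_available(layer.x_eff, device_channel, dens,
                                       0.3).per_sniff
        u_hat, _, _, _ = velocity_phasor(device_channel, air, device_protocol)
        r = np.linspace(0, device_channel.radius, 1000)
        q_amp = abs(2 * math.pi * np.trapezoid(u_hat(r) * r, r))
        advected = dens * q_amp * (2.0 / math.pi) / 0.3  # |sin| mean * period
        assert captured < advected


class TestAmplitudeAndBeta:
    def test_zero_beta_means_zero_amplitude(self):
        assert predicted_amplitude(1e14, 0.0) == 0.0

    def test_amplitude_linear_in_concentration(self, device_channel, air,
                                               device_protocol):
        summaries = [
            deposition_summary(device_channel, air,
                               OdorSource(liquid_volume_fraction=fr),
                               device_protocol, beta=1e-17, n_time=32)
            for fr in (0.1, 0.5, 1.0)]
        base = summaries[0]
        for s, fr in zip(summaries, (0.1, 0.5, 1.0)):
            assert s.predicted_amplitude == pytest.approx(
                base.predicted_amplitude * fr / 0.1, rel=1e-9)

    def test_beta_recovered_from_noisy_observations(self, device_channel, air):
        beta_true = 4.2e-18
        rng = np.random.default_rng(5)
        obs, model_cache = [], {}

        def model(wo, c_ppt):
            key = (round(wo, 6), round(c_ppt, 6))
            if key not in model_cache:
                f = (wo / device_channel.radius) ** 2 * \
                    2 * air.kinematic_viscosity / math.pi
                layer = detected_layer(device_channel, air,
                                       DEVICE_CALIBRATION.protocol(f),
                                       n_time=32)
                dens = headspace_concentration(
                    OdorSource(liquid_volume_fraction=c_ppt / 89.0)
                ).number_density
                model_cache[key] = molecules_available(
                    layer.x_eff, device_channel, dens, f).per_sniff
            return model_cache[key]

        for wo in (1.25, 1.5, 1.65, 1.8):
            for c in (8.9, 44.5, 89.0):
                nd = model(wo, c)
                obs.append((wo, c, beta_true * nd * rng.normal(1.0, 0.03)))
        beta_hat = fit_beta(obs, model)
        assert beta_hat == pytest.approx(beta_true, rel=0.05)

    def test_amplitude_ordering_matches_concentration_curves(
            self, device_channel, air):
        # one beta: A falls with Wo and rises with C, matching the
        # measured concentration-family ordering
        beta = 1e-17
        amps = {}
        for fr in (0.1, 0.5, 1.0):
            source = OdorSource(liquid_volume_fraction=fr)
            for f in (0.14, 0.3):
                s = deposition_summary(device_channel, air, source,
                                       DEVICE_CALIBRATION.protocol(f), beta,
                                       n_time=32)
                amps[(fr, f)] = s.predicted_amplitude
        for f in (0.14, 0.3):
            assert amps[(0.1, f)] < amps[(0.5, f)] < amps[(1.0, f)]
        for fr in (0.1, 0.5, 1.0):
            assert amps[(fr, 0.3)] < amps[(fr, 0.14)]

    def test_fit_beta_validates_inputs(self):
        with pytest.raises(ValueError, match="at least one"):
            fit_beta([], lambda w, c: 1.0)
        with pytest.raises(ValueError, match="zero molecules"):
            fit_beta([(1.0, 10.0, 0.5)], lambda w, c: 0.0)


class TestOptimalFrequency:
    @pytest.fixture
    def grid(self):
        return np.round(np.arange(0.05, 1.01, 0.05), 3)

    def test_calibrated_optimum_is_at_wo_1p8(self, device_channel, air, grid):
        # beta chosen so the lowest concentration meets the noise floor at
        # 0.3 Hz: the fastest feasible sniff is then 0.3 Hz, Wo ~ 1.8
        source = OdorSource(liquid_volume_fraction=0.1)
        dens = headspace_concentration(source).number_density
        layer = detected_layer(device_channel, air,
                               DEVICE_CALIBRATION.protocol(0.3), n_time=64)
        nd = molecules_available(layer.x_eff, device_channel, dens,
                                 0.3).per_sniff
        beta = 0.03 / nd
        report = optimal_frequency(device_channel, air, source, beta,
                                   SniffRegimeLimits(), grid, n_time=64)
        assert report.feasible
        assert report.optimal_frequency == pytest.approx(0.3, abs=1e-9)
        assert report.optimal_womersley == pytest.approx(1.8, abs=0.03)

    def test_zero_noise_floor_selects_fastest_grid_point(self, device_channel,
                                                         air, grid):
        source = OdorSource(liquid_volume_fraction=0.1)
        report = optimal_frequency(device_channel, air, source, beta=1e-30,
                                   limits=SniffRegimeLimits(noise_floor=1e-30),
                                   f_grid=grid, n_time=32)
        assert report.optimal_frequency == pytest.approx(grid.max())

    def test_more_concentration_never_slows_the_optimum(self, device_channel,
                                                        air, grid):
        source_lo = OdorSource(liquid_volume_fraction=0.1)
        dens = headspace_concentration(source_lo).number_density
        layer = detected_layer(device_channel, air,
                               DEVICE_CALIBRATION.protocol(0.3), n_time=32)
        beta = 0.03 / molecules_available(layer.x_eff, device_channel, dens,
                                          0.3).per_sniff
        last = 0.0
        for fr in (0.1, 0.5, 1.0):
            rep = optimal_frequency(device_channel, air,
                                    OdorSource(liquid_volume_fraction=fr),
                                    beta, SniffRegimeLimits(), grid, n_time=32)
            assert rep.feasible and rep.optimal_frequency >= last
            last = rep.optimal_frequency

    def test_infeasible_set_is_reported_not_raised(self, device_channel, air,
                                                   grid):
        source = OdorSource(liquid_volume_fraction=0.1)
        report = optimal_frequency(device_channel, air, source, beta=1e-30,
                                   limits=SniffRegimeLimits(noise_floor=1e3),
                                   f_grid=grid, n_time=32)
        assert not report.feasible
        assert report.optimal_frequency is None
        assert all(r.classification == "below-noise" for r in report.regimes)

    def test_regime_boundary_is_sharp(self, device_channel, air):
        source = OdorSource(liquid_volume_fraction=0.1)
        dens = headspace_concentration(source).number_density
        layer = detected_layer(device_channel, air,
                               DEVICE_CALIBRATION.protocol(0.3), n_time=32)
        nd = molecules_available(layer.x_eff, device_channel, dens,
                                 0.3).per_sniff
        beta = 0.03 / nd
        eps = 1e-9
        above = optimal_frequency(device_channel, air, source, beta,
                                  SniffRegimeLimits(noise_floor=0.03 - eps),
                                  [0.3], n_time=32)
        below = optimal_frequency(device_channel, air, source, beta,
                                  SniffRegimeLimits(noise_floor=0.03 + eps),
                                  [0.3], n_time=32)
        assert above.regimes[0].classification == "operational"
        assert below.regimes[0].classification == "below-noise"


class TestValidation:
    def test_odor_source_fraction_bounds(self):
        with pytest.raises(ValueError):
            OdorSource(liquid_volume_fraction=1.5)

    def test_limits_must_be_positive(self):
        with pytest.raises(ValueError):
            SniffRegimeLimits(noise_floor=0.0)
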