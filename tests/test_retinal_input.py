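"""Retinal input reconstruction, PSD conventions, and the spectral oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftcsf import (
    DiffusionSpec,
    EnvelopeSpec,
    GratingStimulus,
    brute_force_spacetime_spectrum,
    constant_trace,
    contrast_envelope,
    demodulated_signal,
    input_power_spectrum,
    lorentzian_bin_power,
    lorentzian_hwhm,
    lorentzian_prediction,
    power_decomposition,
    simulate_brownian_drift,
    simulate_drift_ensemble,
    temporal_power_spectrum,
)

T_GRID = np.arange(3200) / 1000.0


class TestContrastEnvelope:
    def test_no_ramp_is_flat(self):
        assert np.all(contrast_envelope(T_GRID, EnvelopeSpec(ramp_shape="none")) == 1.0)

    def test_raised_cosine_closed_form(self):
        m = contrast_envelope(T_GRID, EnvelopeSpec("raised_cosine", 0.5))
        assert m[0] == 0.0
        assert m[250] == pytest.approx(0.5, abs=1e-9)  # t = 0.25 s
        assert m[1600] == 1.0  # mid-trial plateau

    def test_linear_ramp_midpoint(self):
        m = contrast_envelope(T_GRID, EnvelopeSpec("linear", 0.5))
        assert m[250] == pytest.approx(0.5, abs=1e-9)
        assert m[1600] == 1.0

    def test_ramps_longer_than_trial_error(self):
        with pytest.raises(ValueError):
            contrast_envelope(T_GRID, EnvelopeSpec("raised_cosine", 2.0))

    @given(
        ramp=st.floats(0.0, 0.4),
        shape=st.sampled_from(["raised_cosine", "linear", "none"]),
        plateau=st.floats(0.1, 1.0),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_bounds_and_symmetry(self, ramp, shape, plateau):
        t = np.arange(1000) / 1000.0
        m = contrast_envelope(t, EnvelopeSpec(shape, ramp, plateau))
        assert np.all(m >= 0.0) and np.all(m <= plateau + 1e-12)
        half = len(t) // 2
        assert np.all(np.diff(m[:half]) >= -1e-12)  # non-decreasing up to mid
        assert np.all(np.diff(m[half:]) <= 1e-12)  # non-increasing after mid
        assert m[half] == pytest.approx(plateau, abs=1e-9)


class TestDemodulatedSignal:
    def test_static_world_is_unity(self):
        tr = constant_trace(1.0, 1000.0)
        stim = GratingStimulus(sf=4.0, duration=1.0, envelope=EnvelopeSpec(ramp_shape="none"))
        assert np.allclose(demodulated_signal(tr, stim), 1.0)

    def test_pure_flicker_concentrates_at_omega(self):
        tr = constant_trace(1.0, 1000.0)
        stim = GratingStimulus(
            sf=4.0, temporal_mod=6.0, duration=1.0, envelope=EnvelopeSpec(ramp_shape="none")
        )
        tf, psd = temporal_power_spectrum(demodulated_signal(tr, stim), 1000.0)
        k = np.argmax(psd)
        assert tf[k] == pytest.approx(6.0)
        assert psd[k] * (tf[1] - tf[0]) == pytest.approx(0.5, rel=1e-9)  # mean sin^2

    def test_linear_drift_doppler_shift(self):
        # drift at 75 arcmin/s along the grating normal, sf=4 -> 5 Hz line
        n = 1000
        t = np.arange(n) / 1000.0
        from driftcsf import EyeTrace

        tr = EyeTrace(t, 75.0 * t, np.zeros(n))
        stim = GratingStimulus(sf=4.0, duration=1.0, envelope=EnvelopeSpec(ramp_shape="none"))
        tf, psd = temporal_power_spectrum(demodulated_signal(tr, stim), 1000.0)
        assert tf[np.argmax(psd)] == pytest.approx(4.0 * 75.0 / 60.0)

    def test_trace_shorter_than_stimulus_errors(self):
        with pytest.raises(ValueError):
            demodulated_signal(constant_trace(0.5, 1000.0), GratingStimulus(sf=1.0, duration=1.0))


class TestTemporalPowerSpectrum:
    def test_constant_signal_all_power_at_dc(self):
        tf, psd = temporal_power_spectrum(np.ones(3200, dtype=complex), 1000.0)
        assert psd[0] * (tf[1] - tf[0]) == pytest.approx(1.0)
        assert np.all(psd[1:] < 1e-20)

    def test_complex_exponential_single_bin(self):
        # 5 Hz is exactly on the 3.2 s grid (bin 16)
        t = np.arange(3200) / 1000.0
        tf, psd = temporal_power_spectrum(np.exp(2j * np.pi * 5.0 * t), 1000.0)
        assert tf[np.argmax(psd)] == pytest.approx(5.0)
        assert psd[np.argmax(psd)] * (tf[1] - tf[0]) == pytest.approx(1.0, rel=1e-9)

    def test_parseval_random_noise(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(4096) + 1j * rng.standard_normal(4096)
        tf, psd = temporal_power_spectrum(z, 1000.0)
        assert psd.sum() * (tf[1] - tf[0]) == pytest.approx(np.mean(np.abs(z) ** 2), rel=1e-10)


class TestInputSpectrum:
    def test_constant_trace_power_only_at_dc(self):
        spec = input_power_spectrum(
            [constant_trace(3.2, 1000.0)],
            GratingStimulus(sf=1.0, envelope=EnvelopeSpec(ramp_shape="none")),
            sf_grid=[0.5, 4.0, 16.0],
            n_orientations=2,
        )
        assert np.all(spec.power[:, 0] > 0)
        assert np.all(spec.power[:, 1:] < 1e-18)

    def test_higher_sf_broader_spectrum(self):
        traces = simulate_drift_ensemble(60, 3.2, 1000.0, DiffusionSpec(250.0, 23))
        spec = input_power_spectrum(
            traces,
            GratingStimulus(sf=1.0, envelope=EnvelopeSpec(ramp_shape="none")),
            sf_grid=[1.0, 8.0],
            n_orientations=4,
        )
        # median frequency of the dynamic power is larger at 8 cpd
        def median_freq(p):
            dyn = p[1:]
            c = np.cumsum(dyn) / dyn.sum()
            return spec.tf_grid[1:][np.searchsorted(c, 0.5)]

        assert median_freq(spec.power[1]) > median_freq(spec.power[0])

    def test_total_power_conserved_across_sf_and_D(self):
        # unit-modulus phase signal: sum P * d_nu == 1 regardless of sf, D
        stim = GratingStimulus(sf=1.0, envelope=EnvelopeSpec(ramp_shape="none"))
        for D, seed in ((250.0, 1), (2.0, 2)):
            traces = simulate_drift_ensemble(3, 3.2, 1000.0, DiffusionSpec(D, seed))
            spec = input_power_spectrum(traces, stim, [0.5, 4.0, 32.0], n_orientations=3)
            totals = spec.power.sum(axis=1) * spec.d_nu
            assert np.all(np.abs(totals - 1.0) < 1e-9)

    def test_empty_trace_list_errors(self):
        with pytest.raises(ValueError):
            input_power_spectrum([], GratingStimulus(sf=1.0), [1.0])

    def test_csv_round_trip(self, tmp_path):
        spec = input_power_spectrum(
            [constant_trace(0.5, 1000.0)], GratingStimulus(sf=1.0, duration=0.5,
            envelope=EnvelopeSpec(ramp_duration=0.1)), [1.0, 2.0], n_orientations=1,
        )
        path = tmp_path / "spec.csv"
        spec.to_csv(path)
        from driftcsf import InputSpectrum

        back = InputSpectrum.from_csv(path)
        assert np.allclose(back.power, spec.power)
        assert np.allclose(back.sf_grid, spec.sf_grid)


class TestLorentzianOracle:
    def test_hwhm_values(self):
        # k = 4*pi^2*sf^2*D/3600; HWHM = k/(2*pi)
        assert lorentzian_hwhm(1.0, 250.0) == pytest.approx(2 * np.pi * 250.0 / 3600.0, rel=1e-12)
        assert lorentzian_hwhm(1.0, 250.0) == pytest.approx(0.436, abs=0.001)
        assert lorentzian_hwhm(8.0, 250.0) == pytest.approx(64 * lorentzian_hwhm(1.0, 250.0))
        assert lorentzian_hwhm(8.0, 250.0) == pytest.approx(27.9, abs=0.05)

    def test_half_maximum_at_hwhm(self):
        psd = lorentzian_prediction(2.0, 250.0)
        nu0 = lorentzian_hwhm(2.0, 250.0)
        assert psd(np.array([nu0]))[0] == pytest.approx(psd(np.array([1e-12]))[0] / 2.0, rel=1e-6)

    def test_unit_total_power(self):
        tf = np.arange(8001) * 0.0625  # 16 s at 1 kHz
        bins = lorentzian_bin_power(3.0, 250.0, tf, aliased=True)
        assert bins.sum() == pytest.approx(1.0, abs=1e-3)


class TestBruteForceOracle:
    def _trace(self):
        return simulate_brownian_drift(0.4, 500.0, DiffusionSpec(250.0, 9))

    def test_static_no_drift_all_power_at_sf_0hz(self):
        tr = constant_trace(0.4, 500.0)
        stim = GratingStimulus(sf=5.0, duration=0.4, envelope=EnvelopeSpec(ramp_shape="none"))
        tf, psd = brute_force_spacetime_spectrum(tr, stim, n_space=32)
        assert psd[0] * (tf[1] - tf[0]) == pytest.approx(1.0)
        assert np.all(psd[1:] < 1e-18)

    @pytest.mark.parametrize("temporal_mod", [0.0, 5.0])
    def test_equals_demodulation_path(self, temporal_mod):
        tr = self._trace()
        stim = GratingStimulus(
            sf=5.0, orientation=0.7, phase=0.3, temporal_mod=temporal_mod,
            duration=0.4, envelope=EnvelopeSpec(ramp_duration=0.05),
        )
        tf1, p1 = temporal_power_spectrum(demodulated_signal(tr, stim), tr.fs)
        tf2, p2 = brute_force_spacetime_spectrum(tr, stim, n_space=64)
        assert np.allclose(tf1, tf2)
        assert np.max(np.abs(p1 - p2)) <= 1e-8 * p1.max()

    def test_pure_flicker_at_sf_and_omega(self):
        tr = constant_trace(0.4, 500.0)
        stim = GratingStimulus(
            sf=5.0, temporal_mod=5.0, duration=0.4, envelope=EnvelopeSpec(ramp_shape="none")
        )
        tf, psd = brute_force_spacetime_spectrum(tr, stim, n_space=32)
        assert tf[np.argmax(psd)] == pytest.approx(5.0)

    def test_non_integer_cycles_errors(self):
        tr = constant_trace(0.4, 500.0)
        stim = GratingStimulus(sf=5.0, duration=0.4)
        with pytest.raises(ValueError):
            brute_force_spacetime_spectrum(tr, stim, n_space=32, spatial_extent=0.3)


class TestPowerDecomposition:
    def test_no_drift_static_has_zero_dynamic_power(self):
        spec = input_power_spectrum(
            [constant_trace(3.2, 1000.0)],
            GratingStimulus(sf=1.0, envelope=EnvelopeSpec(ramp_shape="none")),
            [0.5, 4.0],
            n_orientations=1,
        )
        dec = power_decomposition(spec)
        assert np.all(dec.dynamic_power < 1e-18)

    def test_dc_plus_dynamic_equals_total(self):
        traces = simulate_drift_ensemble(10, 3.2, 1000.0, DiffusionSpec(250.0, 4))
        spec = input_power_spectrum(
            traces, GratingStimulus(sf=1.0, envelope=EnvelopeSpec(ramp_shape="none")),
            [0.5, 4.0, 16.0], n_orientations=2,
        )
        dec = power_decomposition(spec, cutoff=spec.tf_grid[1])
        assert np.allclose(dec.dc_power + dec.dynamic_power, 1.0, rtol=1e-9)

    def test_dynamic_power_increases_with_sf_under_drift(self):
        # drift converts more DC power into dynamic power at higher sf
        traces = simulate_drift_ensemble(200, 3.2, 1000.0, DiffusionSpec(250.0, 3))
        sf_grid = np.geomspace(0.1, 30.0, 24)
        spec = input_power_spectrum(
            traces, GratingStimulus(sf=1.0, envelope=EnvelopeSpec(ramp_shape="none")),
            sf_grid, n_orientations=4,
        )
        dec = power_decomposition(spec, cutoff=spec.tf_grid[1])
        assert np.all(np.diff(dec.dynamic_power) > 0)
        assert np.all(np.diff(dec.dc_power) < 0)

    def test_increasing_D_never_increases_dc_power(self):
        stim = GratingStimulus(sf=1.0, envelope=EnvelopeSpec(ramp_shape="none"))
        sf_grid = [0.5, 2.0, 8.0]
        dcs = []
        for D, seed in ((50.0, 6), (250.0, 7)):
            traces = simulate_drift_ensemble(200, 3.2, 1000.0, DiffusionSpec(D, seed))
            spec = input_power_spectrum(traces, stim, sf_grid, n_orientations=2)
            dcs.append(power_decomposition(spec).dc_power)
        assert np.all(dcs[1] < dcs[0])
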