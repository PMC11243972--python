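"""Signal-processing chain: range FFT, phase chain, denoisers, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respiradar import (BandpassSpec, BreathingPattern, PatternClass,
                        PhaseSeries, PhaseState, RadarConfig, RespWaveform,
                        SceneConfig, average_phase_cancellation,
                        design_bandpass, extract_phase, extract_respiration,
                        moving_target_indication, phase_difference, range_fft,
                        select_range_bin, spectral_estimate,
                        superpose_antennas, synthesize_cube, unwrap_phase)
from respiradar.vitals_dsp import (apply_bandpass, denoiser_benchmark,
                                   measure_band_edges, reference_waveform,
                                   residual_noise_power, slow_time_series)
from respiradar.synthetic_radar import if_sample


def _static_cube(radar, reflectors):
    """Cube of stationary reflectors [(range, amplitude), ...] built directly."""
    from respiradar import IFDataCube

    n_frames = 40
    t_fast = np.arange(radar.samples_per_chirp) / radar.fast_time_rate
    samples = np.zeros((n_frames, radar.chirps_per_frame,
                        radar.samples_per_chirp, radar.n_rx), dtype=complex)
    for rng_m, amp in reflectors:
        samples += if_sample(t_fast[None, None, :, None], rng_m, radar, amp)
    return IFDataCube(samples=samples, radar_config=radar,
                      timestamps=np.arange(n_frames) * radar.frame_duration)


class TestRangeFFT:
    def test_single_reflector_lands_in_expected_bin(self, radar):
        for rng_m in (0.4, 0.8, 1.5):
            cube = _static_cube(radar, [(rng_m, 1.0)])
            profile = range_fft(cube)
            peak = int(np.argmax(profile.magnitudes.mean(axis=(0, 1, 3))))
            assert peak == round(rng_m / profile.bin_spacing)

    def test_zero_cube_gives_zero_profile(self, radar):
        cube = _static_cube(radar, [])
        assert np.all(range_fft(cube).values == 0)

    def test_two_reflectors_match_naive_dft(self, radar):
        """2:1 reflectors produce 2:1 maxima, checked against a DFT-sum oracle."""
        cube = _static_cube(radar, [(0.6, 2.0), (1.5, 1.0)])
        profile = range_fft(cube)
        row = cube.samples[0, 0, :, 0]
        n = len(row)
        # naive DFT of the conjugated samples, summed term by term
        oracle = np.array([sum(np.conj(row[m]) * np.exp(-2j * np.pi * k * m / n)
                               for m in range(n)) for k in range(n)])
        assert np.allclose(profile.values[0, 0, :, 0], oracle, atol=1e-8)
        mags = profile.magnitudes.mean(axis=(0, 1, 3))
        b1 = round(0.6 / profile.bin_spacing)
        b2 = round(1.5 / profile.bin_spacing)
        assert mags[b1] / mags[b2] == pytest.approx(2.0, rel=0.1)


class TestSelectRangeBin:
    def test_picks_target_not_far_clutter(self, radar):
        cube = _static_cube(radar, [(0.8, 1.0), (2.5, 5.0)])
        profile = range_fft(cube)
        bin_idx = select_range_bin(profile, (0.3, 2.0))
        assert bin_idx == round(0.8 / profile.bin_spacing)

    @pytest.mark.parametrize("rng_m", [0.4, 0.8, 1.5])
    def test_selected_bin_scales_with_range(self, radar, rng_m):
        cube = _static_cube(radar, [(rng_m, 1.0)])
        profile = range_fft(cube)
        assert select_range_bin(profile) == round(rng_m / profile.bin_spacing)

    def test_degenerate_inputs_rejected(self, radar):
        profile = range_fft(_static_cube(radar, []))
        with pytest.raises(ValueError):
            select_range_bin(profile)                  # no energy
        with pytest.raises(ValueError):
            select_range_bin(profile, (0.001, 0.002))  # empty window


class TestPhaseChain:
    def test_constant_positive_bin_gives_zero_phase(self, radar):
        cube = _static_cube(radar, [])
        profile = range_fft(cube)
        profile.values[:, :, 5, :] = 3.0  # real positive constant
        series = extract_phase(profile, 5)
        assert np.all(series.values == 0)
        assert series.state is PhaseState.WRAPPED

    def test_lambda_eighth_step_gives_half_pi(self, radar):
        # displacement step lambda/8 between frames -> phase step
        # 4*pi*(lambda/8)/lambda = pi/2 (displacement-phase arithmetic)
        steps = np.exp(1j * (np.pi / 2) * np.arange(6))
        profile = range_fft(_static_cube(radar, []))
        profile.values = np.zeros((6, 2, profile.n_bins, 4), dtype=complex)
        profile.values[:, :, 7, :] = steps[:, None, None]
        series = extract_phase(profile, 7)
        d = np.diff(np.unwrap(series.values[:, 0]))
        assert np.allclose(d, np.pi / 2, atol=1e-12)

    def test_noiseless_breathing_phase_is_periodic(self, radar, clean_scene):
        # 0.25 Hz puts one breathing period on exactly 80 frames
        pattern = BreathingPattern(PatternClass.NORMAL, amplitude=0.004,
                                   rate=0.25, shape_exponent=2.0)
        cube = synthesize_cube(pattern, clean_scene, radar, 12.0)
        profile = range_fft(cube)
        series = extract_phase(profile, select_range_bin(profile))
        unwrapped = unwrap_phase(series).values[:, 0]
        assert np.allclose(unwrapped[80:], unwrapped[:-80], atol=1e-9)

    def test_unwrap_identity_and_ramp(self):
        smooth = PhaseSeries(np.linspace(-1, 1, 50), 20.0, PhaseState.WRAPPED)
        assert np.array_equal(unwrap_phase(smooth).values, smooth.values)
        ramp = 0.4 * np.arange(100)
        wrapped = np.angle(np.exp(1j * ramp))
        out = unwrap_phase(PhaseSeries(wrapped, 20.0, PhaseState.WRAPPED))
        assert np.allclose(out.values, ramp, atol=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=-3.0, max_value=3.0), min_size=2,
                    max_size=60))
    def test_unwrap_matches_bruteforce_oracle(self, steps):
        """Random-walk phase with injected wraps vs cumulative-correction loop."""
        true_phase = np.cumsum(steps)
        wrapped = np.angle(np.exp(1j * true_phase))
        # independent oracle: walk the series, correcting by +-2*pi
        oracle = [wrapped[0]]
        for v in wrapped[1:]:
            prev = oracle[-1]
            d = v - prev
            while d > np.pi:
                d -= 2 * np.pi
            while d < -np.pi:
                d += 2 * np.pi
            oracle.append(prev + d)
        out = unwrap_phase(PhaseSeries(wrapped, 20.0, PhaseState.WRAPPED))
        assert np.allclose(out.values, oracle, atol=1e-9)

    def test_difference_removes_drift_exactly(self):
        t = np.arange(200) / 20.0
        base = np.sin(2 * np.pi * 0.3 * t)
        for slope in (0.0, 0.7, -123.4):
            series = PhaseSeries(base + slope * t, 20.0, PhaseState.UNWRAPPED)
            out = phase_difference(series).values - slope / 20.0
            ref = np.diff(base)
            assert np.allclose(out, ref, atol=1e-10)

    def test_difference_of_sinusoid_scales_and_shifts(self):
        fs, fr = 20.0, 0.3
        t = np.arange(2000) / fs
        series = PhaseSeries(np.sin(2 * np.pi * fr * t), fs, PhaseState.UNWRAPPED)
        out = phase_difference(series).values
        # amplitude 2*sin(pi*fr/fs) ~ 2*pi*fr/fs, quadrature phase
        assert np.max(np.abs(out)) == pytest.approx(2 * np.sin(np.pi * fr / fs),
                                                    rel=1e-3)
        assert np.allclose(out, np.diff(series.values))  # direct-difference oracle

    def test_state_machine_enforced(self):
        wrapped = PhaseSeries(np.zeros(10), 20.0, PhaseState.WRAPPED)
        with pytest.raises(ValueError):
            phase_difference(wrapped)
        unwrapped = unwrap_phase(wrapped)
        with pytest.raises(ValueError):
            unwrap_phase(unwrapped)
        with pytest.raises(ValueError):
            phase_difference(PhaseSeries(np.zeros(1), 20.0, PhaseState.UNWRAPPED))


class TestAntennaCombining:
    def test_identical_channels_coherent_gain(self):
        x = np.exp(1j * np.sin(np.linspace(0, 20, 300)))
        out = superpose_antennas(np.stack([x] * 4, axis=1))
        assert np.allclose(out, 4 * x, atol=1e-9)
        # power grows as K^2
        assert np.mean(np.abs(out) ** 2) == pytest.approx(
            16 * np.mean(np.abs(x) ** 2), rel=1e-9)

    def test_known_phase_offsets_recovered(self):
        x = np.exp(1j * np.sin(np.linspace(0, 20, 500)))
        offs = [0.0, np.pi / 3, -np.pi / 2, np.pi]
        chans = np.stack([x * np.exp(1j * o) for o in offs], axis=1)
        out = superpose_antennas(chans)
        assert np.max(np.abs(np.abs(out) - 4 * np.abs(x))) < 1e-9

    def test_known_integer_lag_recovered(self):
        rng = np.random.default_rng(0)
        x = np.exp(1j * np.cumsum(rng.normal(scale=0.3, size=400)))
        chans = np.stack([x, np.roll(x, 3)], axis=1)
        out = superpose_antennas(chans)
        assert np.mean(np.abs(out) ** 2) == pytest.approx(
            4 * np.mean(np.abs(x) ** 2), rel=1e-2)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            superpose_antennas([np.ones(10, complex), np.ones(9, complex)])

    def test_apc_removes_static_component(self, radar):
        cube = _static_cube(radar, [(1.0, 2.0)])
        profile = range_fft(cube)
        b = round(1.0 / profile.bin_spacing)
        out = average_phase_cancellation(slow_time_series(profile, b))
        assert np.max(np.abs(out)) < 1e-9
        # static + breathing: DC gone, breathing kept
        t = np.arange(500)
        breathing = 0.5 * np.exp(1j * 0.8 * np.sin(2 * np.pi * 0.014 * t))
        chans = np.stack([3.0 + breathing] * 4, axis=1)
        out = average_phase_cancellation(chans)
        assert abs(np.mean(out)) < 1e-9
        assert np.std(out) > 0.1

    def test_mti_closed_form_response(self):
        fs = 20.0
        k = np.arange(4000)
        for f in (0.1, 0.5, 2.0, 7.0):
            x = np.exp(2j * np.pi * f * k / fs)
            y = moving_target_indication(x)
            gain = np.mean(np.abs(y)) / np.mean(np.abs(x))
            assert gain == pytest.approx(abs(1 - np.exp(-2j * np.pi * f / fs)),
                                         rel=1e-6)
        # constant input cancels exactly; a DC offset contributes nothing
        assert np.allclose(moving_target_indication(np.full(50, 2 + 1j)), 0)
        tone = np.exp(2j * np.pi * 0.3 * k / fs)
        assert np.allclose(moving_target_indication(5.0 + tone),
                           moving_target_indication(tone), atol=1e-12)


class TestBandpass:
    @staticmethod
    def _tone_amplitude(x, f, fs):
        # projection onto the tone, immune to the filter's slowly decaying
        # passband edge transients
        t = np.arange(len(x)) / fs
        return 2 * abs(np.mean(x * np.exp(-2j * np.pi * f * t)))

    def test_passband_and_stopband(self):
        fs = 20.0
        sos = design_bandpass(fs)
        t = np.arange(int(120 * fs)) / fs
        out = apply_bandpass(np.sin(2 * np.pi * 0.3 * t), sos)
        gain_db = 20 * np.log10(self._tone_amplitude(out, 0.3, fs))
        assert abs(gain_db) < 1.0               # forward-backward: 2x ripple
        out = apply_bandpass(np.sin(2 * np.pi * 2.0 * t), sos)
        atten_db = -20 * np.log10(self._tone_amplitude(out, 2.0, fs) + 1e-300)
        assert atten_db >= 40.0

    def test_white_noise_power_confined_to_band(self):
        fs = 20.0
        sos = design_bandpass(fs)
        rng = np.random.default_rng(1)
        x = rng.normal(size=int(600 * fs))
        y = apply_bandpass(x, sos)
        spec = np.abs(np.fft.rfft(y)) ** 2
        freqs = np.fft.rfftfreq(len(y), 1 / fs)
        frac = spec[(freqs >= 0.08) & (freqs <= 0.52)].sum() / spec.sum()
        assert frac >= 0.90

    def test_band_edges_at_design_frequencies(self):
        spec = BandpassSpec()
        sos = design_bandpass(20.0, spec)
        lo, hi = measure_band_edges(sos, 20.0, spec.passband_ripple)
        assert lo == pytest.approx(0.1, rel=0.01)
        assert hi == pytest.approx(0.5, rel=0.01)

    def test_zero_phase_no_lag(self):
        fs = 20.0
        sos = design_bandpass(fs)
        t = np.arange(int(200 * fs)) / fs
        x = np.sin(2 * np.pi * 0.28 * t)
        y = apply_bandpass(x, sos)
        corr = np.correlate(y[200:-200], x[200:-200], "full")
        lag = np.argmax(corr) - (len(x) - 401)
        assert lag == 0

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            design_bandpass(0.8, BandpassSpec())   # high_cut above Nyquist


class TestExtractRespiration:
    def test_noiseless_cube_recovers_rate(self, noiseless_cube):
        wave = extract_respiration(noiseless_cube)
        assert spectral_estimate(wave) == pytest.approx(0.28, abs=0.02)

    def test_waveform_matches_reference_shape(self, noiseless_cube, radar,
                                              breathing_pattern):
        wave = extract_respiration(noiseless_cube)
        ref = reference_waveform(breathing_pattern, radar, 25.0)
        n = min(len(wave.values), len(ref.values))
        rho = np.corrcoef(wave.values[:n], ref.values[:n])[0, 1]
        assert abs(rho) > 0.99

    def test_static_scene_gives_near_zero_waveform(self, radar, noiseless_cube):
        # breath-hold target: chest effectively motionless
        still = BreathingPattern(PatternClass.NORMAL, amplitude=1e-12, rate=0.28)
        scene = SceneConfig(target_range=0.8, snr_db=20.0, seed=5)
        cube = synthesize_cube(still, scene, radar, 25.0)
        quiet = extract_respiration(cube)
        breathing = extract_respiration(noiseless_cube)
        assert np.max(np.abs(quiet.values)) < 0.05 * np.max(np.abs(breathing.values))

    @pytest.mark.parametrize("seed", range(5))
    def test_quick_breathing_recovered_under_noise(self, radar, seed):
        pattern = BreathingPattern(PatternClass.QUICK, amplitude=0.003,
                                   rate=0.45, shape_exponent=2.0)
        scene = SceneConfig(snr_db=10.0, seed=seed)
        cube = synthesize_cube(pattern, scene, radar, 25.0)
        wave = extract_respiration(cube)
        assert spectral_estimate(wave) == pytest.approx(0.45, abs=0.02)

    def test_denoiser_partial_ordering(self):
        """Overlay is the best front-end; raw with in-bin clutter the worst."""
        res = denoiser_benchmark(n_seeds=6, seed=100)
        assert res["overlay"] < res["apc"] < res["raw"]
        assert res["overlay"] < res["mti"] < res["raw"]


class TestSpectralEstimate:
    def test_pure_tone(self):
        fs = 20.0
        t = np.arange(int(25 * fs)) / fs
        wave = RespWaveform(np.sin(2 * np.pi * 0.28 * t), fs)
        assert spectral_estimate(wave) == pytest.approx(0.28, abs=0.02)

    def test_dominant_of_two_tones(self):
        fs = 20.0
        t = np.arange(int(60 * fs)) / fs
        wave = RespWaveform(np.sin(2 * np.pi * 0.2 * t)
                            + 0.3 * np.sin(2 * np.pi * 0.4 * t), fs)
        assert spectral_estimate(wave) == pytest.approx(0.2, abs=0.02)

    def test_out_of_band_tone_flagged(self):
        fs = 20.0
        t = np.arange(int(60 * fs)) / fs
        wave = RespWaveform(np.sin(2 * np.pi * 1.5 * t), fs)
        assert np.isnan(spectral_estimate(wave))

    def test_all_zero_flagged(self):
        assert np.isnan(spectral_estimate(RespWaveform(np.zeros(500), 20.0)))


def test_residual_noise_power_endpoints():
    fs = 20.0
    t = np.arange(int(30 * fs)) / fs
    ref = RespWaveform(np.sin(2 * np.pi * 0.25 * t), fs)
    same = RespWaveform(3.7 * np.sin(2 * np.pi * 0.25 * t), fs)
    assert residual_noise_power(same, ref) < 1e-9
    rng = np.random.default_rng(0)
    noise = RespWaveform(rng.normal(size=len(t)), fs)
    assert residual_noise_power(noise, ref) > 0.9
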