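"""Structural, spectral and determinism properties of the synthetic pulse train."""

import numpy as np
import pytest

from cnpsim.signal_gen import (
    SignalSpec,
    SignalConfigError,
    SampledSignal,
    generate_cnp,
    precondition,
    derive_and_scale,
    make_uniform_pulse_variant,
    invert_lag_order,
    tile_pattern,
    detect_pulse_times,
    count_pulse_couples,
    signal_minimum_times,
    make_forcing,
)


class TestSpecValidation:
    def test_refractory_length_mismatch_rejected(self):
        with pytest.raises(SignalConfigError):
            SignalSpec(refractory_periods=(110.0, 220.0, 330.0))

    def test_pulses_that_do_not_fit_rejected(self):
        with pytest.raises(SignalConfigError):
            SignalSpec(pulse_width=60.0)  # 16 x 60 ms > 838 ms

    @pytest.mark.parametrize("field,value", [
        ("latency_growth", -0.5),
        ("jitter_fraction", 0.5),
        ("jitter_fraction", -0.1),
    ])
    def test_out_of_range_parameters_rejected(self, field, value):
        with pytest.raises(SignalConfigError):
            SignalSpec(**{field: value})


class TestPatternTiming:
    def test_basic_pattern_lasts_5212_ms(self, default_spec, default_pattern):
        assert default_spec.pattern_duration == 5212.0
        assert default_pattern.duration == pytest.approx(5212.0)

    def test_burst_tiling_is_exact(self, default_spec):
        lat = default_spec.latencies()
        total = default_spec.pulses_per_burst * default_spec.pulse_width + lat.sum()
        assert total == pytest.approx(default_spec.burst_duration, abs=1e-9)

    def test_latencies_strictly_increase_for_positive_growth(self, default_spec):
        lat = default_spec.latencies()
        assert np.all(np.diff(lat) > 0)

    def test_fourth_refractory_period_is_1200_ms(self, default_spec):
        assert default_spec.refractory_periods[3] == 1200.0

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("jitter", [0.0, 0.1, 0.2])
    def test_sixteen_pulse_couples_detected_per_burst(self, seed, jitter):
        spec = SignalSpec(jitter_fraction=jitter, seed=seed)
        assert count_pulse_couples(generate_cnp(spec), spec) == [16, 16, 16, 16]

    def test_uniform_degenerate_case_equally_spaced_identical_pulses(self):
        spec = SignalSpec(jitter_fraction=0.0, latency_growth=0.0)
        lat = spec.latencies()
        assert np.ptp(lat) == pytest.approx(0.0, abs=1e-9)
        sig = generate_cnp(spec)
        times = detect_pulse_times(sig)
        burst1 = times[:16]
        gaps = np.diff(burst1)
        assert np.allclose(gaps, gaps.mean(), atol=1.1)  # equal to sample accuracy


class TestDeterminismAndVariants:
    def test_identical_spec_gives_bit_identical_output(self):
        a = generate_cnp(SignalSpec(seed=5))
        b = generate_cnp(SignalSpec(seed=5))
        assert np.array_equal(a.values, b.values)

    def test_different_seed_changes_jittered_output(self):
        a = generate_cnp(SignalSpec(seed=5))
        b = generate_cnp(SignalSpec(seed=6))
        assert not np.array_equal(a.values, b.values)

    def test_uniform_pulse_variant_has_original_timing_and_duration(self, default_spec):
        var = make_uniform_pulse_variant(default_spec, 9)
        orig = generate_cnp(default_spec)
        assert var.duration == orig.duration
        assert np.allclose(detect_pulse_times(var), detect_pulse_times(orig), atol=1.5)

    def test_uniform_pulse_variant_repeats_one_waveform(self):
        # burst length chosen so the uniform latency (52 ms) is grid-aligned
        # and every pulse window therefore holds identical samples
        spec = SignalSpec(burst_duration=844.0, latency_growth=0.0,
                          jitter_fraction=0.2, seed=2)
        var = make_uniform_pulse_variant(spec, 9)
        period = int(spec.pulse_width + spec.latencies()[0])
        first = var.values[: int(spec.pulse_width)]
        for p in range(1, 16):
            start = p * period
            np.testing.assert_allclose(
                var.values[start:start + int(spec.pulse_width)], first, atol=1e-12)

    def test_uniform_variant_of_jitterless_source_is_identity(self, ):
        spec = SignalSpec(jitter_fraction=0.0)
        for idx in (1, 9, 16):
            var = make_uniform_pulse_variant(spec, idx)
            np.testing.assert_array_equal(var.values, generate_cnp(spec).values)

    def test_pulse_index_out_of_range_rejected(self, default_spec):
        with pytest.raises(SignalConfigError):
            make_uniform_pulse_variant(default_spec, 17)
        with pytest.raises(SignalConfigError):
            make_uniform_pulse_variant(default_spec, 0)

    def test_inverted_refractory_order_preserves_duration(self, default_spec):
        inv = invert_lag_order(default_spec, "refractory")
        assert inv.duration == pytest.approx(5212.0)
        # burst starts now follow gaps 1200, 330, 220 (110 trails the pattern)
        times = detect_pulse_times(inv)
        burst_starts = times[::16][:4]
        gaps = np.diff(burst_starts) - default_spec.burst_duration
        np.testing.assert_allclose(gaps, [1200.0, 330.0, 220.0], atol=2.0)

    def test_latency_inversion_with_uniform_latencies_is_identity(self):
        spec = SignalSpec(latency_growth=0.0)
        inv = invert_lag_order(spec, "latency")
        np.testing.assert_array_equal(inv.values, generate_cnp(spec).values)

    def test_double_latency_inversion_changes_nothing_detectable(self, default_spec):
        # inversion is an involution on the latency sequence
        lat = default_spec.latencies()
        np.testing.assert_array_equal(lat[::-1][::-1], lat)
        inv = invert_lag_order(default_spec, "latency")
        orig = generate_cnp(default_spec)
        assert inv.duration == orig.duration
        assert not np.array_equal(inv.values, orig.values)

    def test_unknown_lag_kind_rejected(self, default_spec):
        with pytest.raises(SignalConfigError):
            invert_lag_order(default_spec, "bursts")


class TestPrecondition:
    def test_upsampling_by_100_multiplies_length(self, default_pattern):
        out = precondition(default_pattern, target_dt=0.01)
        assert len(out.values) == 100 * len(default_pattern.values)
        assert out.dt == 0.01

    def test_dc_input_passes_with_unity_gain(self):
        const = SampledSignal(dt=1.0, values=np.full(2000, 3.7))
        out = precondition(const, target_dt=0.01)
        # after the filter settles the DC level is preserved
        assert np.allclose(out.values[-1000:], 3.7, atol=1e-6)

    def test_1khz_tone_attenuated_per_butterworth_magnitude(self):
        # |H(f)| = 1/sqrt(1 + (f/fc)^(2n)) at f=1000, fc=500, n=5 -> 0.03123
        dt = 0.01
        t = dt * np.arange(400_000)
        tone = SampledSignal(dt=0.1, values=np.sin(2 * np.pi * 1.0 * 0.1
                                                   * np.arange(40_000)))
        out = precondition(tone, target_dt=dt, corner_hz=500.0, order=5)
        # steady-state amplitude over the last quarter
        amp = np.max(np.abs(out.values[-100_000:]))
        expected = 1.0 / np.sqrt(1.0 + (1000.0 / 500.0) ** 10)
        assert amp == pytest.approx(expected, rel=0.05)

    def test_energy_above_two_corners_drops_at_least_28_db(self, default_pattern):
        from scipy.signal import periodogram
        up = precondition(default_pattern, target_dt=0.01, corner_hz=500.0)
        # compare filtered spectrum against the unfiltered upsampled signal
        t_old = np.arange(len(default_pattern.values)) * 1.0
        t_new = 0.01 * np.arange(len(default_pattern.values) * 100)
        raw_up = np.interp(t_new, t_old, default_pattern.values)
        fs = 100_000.0
        f, p_raw = periodogram(raw_up, fs=fs)
        _, p_fil = periodogram(up.values, fs=fs)
        band = (f > 1000.0) & (f < 5000.0)
        drop_db = 10 * np.log10(p_raw[band].sum() / p_fil[band].sum())
        assert drop_db >= 28.0

    def test_invalid_resampling_requests_rejected(self, default_pattern):
        with pytest.raises(ValueError):
            precondition(default_pattern, target_dt=2.0)
        with pytest.raises(ValueError):
            precondition(default_pattern, target_dt=0.3)  # does not divide 1 ms
        with pytest.raises(ValueError):
            precondition(default_pattern, target_dt=0.5, corner_hz=1500.0)


class TestDeriveAndScale:
    def test_peak_equals_requested_amplitude(self, default_pattern):
        for amp in (0.1, 0.8, 8.0):
            out = derive_and_scale(precondition(default_pattern, 0.01), amp)
            assert np.max(np.abs(out.values)) == pytest.approx(amp, rel=1e-9)

    def test_linear_ramp_gives_constant_derivative(self):
        ramp = SampledSignal(dt=0.01, values=np.linspace(0.0, 1.0, 1000))
        out = derive_and_scale(ramp, 0.5)
        np.testing.assert_allclose(out.values, 0.5, atol=1e-9)

    def test_sinusoid_derivative_is_quarter_period_advanced(self):
        dt, f_hz = 0.01, 20.0
        t = dt * np.arange(50_000)  # ms
        sig = SampledSignal(dt=dt, values=np.sin(2 * np.pi * f_hz * t / 1000.0))
        out = derive_and_scale(sig, 1.0)
        period_ms = 1000.0 / f_hz
        # derivative peaks where the sine crosses zero going up
        peak_t = t[np.argmax(out.values[:int(period_ms / dt)])]
        sine_peak_t = t[np.argmax(sig.values[:int(period_ms / dt)])]
        assert (sine_peak_t - peak_t) == pytest.approx(period_ms / 4, abs=2 * dt)

    def test_constant_input_cannot_be_normalized(self):
        const = SampledSignal(dt=0.01, values=np.ones(100))
        with pytest.raises(ValueError):
            derive_and_scale(const, 1.0)


class TestPipelineAndIO:
    def test_forcing_pipeline_peak_and_step(self, default_spec):
        f = make_forcing(default_spec, 0.8, 8000.0)
        assert f.dt == 0.01
        assert len(f.values) == 800_000
        assert np.max(np.abs(f.values)) == pytest.approx(0.8, rel=1e-9)

    def test_tiling_repeats_pattern_to_duration(self, default_pattern):
        tiled = tile_pattern(default_pattern, 12_000.0)
        assert len(tiled.values) == 12_000
        np.testing.assert_array_equal(tiled.values[:5212], default_pattern.values)
        np.testing.assert_array_equal(tiled.values[5212:10424],
                                      default_pattern.values)

    def test_minimum_peak_times_follow_pulse_grid(self, default_spec):
        f = make_forcing(default_spec, 1.0, 5212.0)
        mins = signal_minimum_times(f)
        pat = detect_pulse_times(generate_cnp(default_spec))
        assert len(mins) == len(pat) == 64
        # derivative minima sit inside their pulse windows
        assert np.all(np.abs(mins - pat) < default_spec.pulse_width)

    def test_text_roundtrip(self, tmp_path, default_pattern):
        p = tmp_path / "sig.txt"
        default_pattern.save_txt(p)
        back = SampledSignal.load_txt(p)
        assert back.dt == default_pattern.dt
        np.testing.assert_allclose(back.values, default_pattern.values, atol=1e-6)

    def test_npz_roundtrip(self, tmp_path, forcing_10s):
        p = tmp_path / "f.npz"
        forcing_10s.save_npz(p)
        back = SampledSignal.load_npz(p)
        assert back.dt == forcing_10s.dt
        np.testing.assert_array_equal(back.values, forcing_10s.values)
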