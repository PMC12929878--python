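"""Level calibration, SNR mixing, silence padding, and WAV round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from auditest import (
    HeadroomError,
    LevelSpec,
    UndefinedLevelError,
    Waveform,
    calibrate_rms,
    mix_at_snr,
    prepend_silence,
    read_wav,
    rms_dbfs,
    write_wav,
)


class TestRmsDbfs:
    def test_full_scale_constant_is_zero_dbfs(self):
        w = Waveform(np.ones(1000), 44_100)
        assert rms_dbfs(w) == pytest.approx(0.0, abs=1e-12)

    def test_full_scale_sine_is_minus_3dbfs(self, sine):
        # RMS of a sine is A/sqrt(2): 20*log10(1/sqrt 2) = -3.0103 dB
        assert rms_dbfs(sine(1000.0, amplitude=1.0)) == pytest.approx(-3.0103, abs=1e-4)

    def test_all_zero_signal_rejected(self):
        with pytest.raises(UndefinedLevelError):
            rms_dbfs(Waveform(np.zeros(100), 44_100))


class TestCalibrateRms:
    def test_sine_gain_to_minus_25(self, sine):
        # gain = 10**((-25 + 3.0103)/20) ≈ 0.07944
        out = calibrate_rms(sine(500.0, amplitude=1.0), LevelSpec(-25.0))
        assert rms_dbfs(out) == pytest.approx(-25.0, abs=1e-9)
        assert out.peak == pytest.approx(0.07944, abs=1e-4)

    def test_quiet_constant_scaled_up(self):
        # 0.001 amplitude sits at -60 dB FS; gain to -25 is 10**(35/20) ≈ 56.234
        w = Waveform(np.full(100, 0.001), 8000)
        out = calibrate_rms(w, LevelSpec(-25.0))
        assert out.samples[0] == pytest.approx(0.001 * 56.2341, rel=1e-4)

    def test_idempotent(self, sine):
        spec = LevelSpec(-25.0)
        once = calibrate_rms(sine(250.0), spec)
        twice = calibrate_rms(once, spec)
        assert rms_dbfs(twice) == pytest.approx(-25.0, abs=1e-9)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-15)

    def test_shape_preserved_up_to_positive_scale(self, sine):
        w = sine(250.0, amplitude=0.3)
        out = calibrate_rms(w, LevelSpec(-25.0))
        ratio = out.samples[w.samples != 0] / w.samples[w.samples != 0]
        assert np.all(ratio > 0)
        assert np.ptp(ratio) < 1e-12

    def test_clipping_raises_headroom_error(self):
        # peaky signal: one big sample, tiny RMS → calibration would clip
        samples = np.full(10_000, 1e-4)
        samples[0] = 0.9
        with pytest.raises(HeadroomError, match="dB"):
            calibrate_rms(Waveform(samples, 44_100), LevelSpec(-10.0))

    def test_zero_input_rejected(self):
        with pytest.raises(UndefinedLevelError):
            calibrate_rms(Waveform(np.zeros(10), 8000), LevelSpec(-25.0))

    def test_level_spec_rejects_nonnegative_target(self):
        with pytest.raises(ValueError):
            LevelSpec(0.0)

    @given(target=st.floats(min_value=-60.0, max_value=-20.0), seed=st.integers(0, 2**16))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_hits_any_target_exactly(self, target, seed):
        rng = np.random.default_rng(seed)
        w = Waveform(rng.standard_normal(500) * 0.05, 8000)
        assert rms_dbfs(calibrate_rms(w, LevelSpec(target))) == pytest.approx(target, abs=1e-9)


class TestMixAtSnr:
    def _measure_snr(self, mixed, speech, gain_noise):
        return rms_dbfs(speech) - rms_dbfs(gain_noise)

    def test_equal_levels_at_0db_gain_is_unity(self, sine, rate):
        rng = np.random.default_rng(0)
        speech = calibrate_rms(sine(1000.0), LevelSpec(-25.0))
        noise = calibrate_rms(Waveform(rng.standard_normal(speech.n_samples), rate), LevelSpec(-25.0))
        mixed = mix_at_snr(speech, noise, 0.0)
        np.testing.assert_allclose(mixed.samples, speech.samples + noise.samples, atol=1e-12)

    @pytest.mark.parametrize("snr_db,expected_gain", [(5.0, 0.5623413), (20.0, 0.1)])
    def test_equal_rms_inputs_noise_gain(self, sine, rate, snr_db, expected_gain):
        rng = np.random.default_rng(1)
        speech = calibrate_rms(sine(1000.0), LevelSpec(-25.0))
        noise = calibrate_rms(Waveform(rng.standard_normal(speech.n_samples), rate), LevelSpec(-25.0))
        mixed = mix_at_snr(speech, noise, snr_db)
        noise_part = mixed.samples - speech.samples
        gain = noise_part / noise.samples
        assert np.median(gain) == pytest.approx(expected_gain, rel=1e-6)

    @given(snr_db=st.floats(min_value=-20, max_value=20), seed=st.integers(0, 2**16))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_realized_snr_exact(self, snr_db, seed):
        rng = np.random.default_rng(seed)
        speech = Waveform(rng.standard_normal(400) * 0.01, 8000)
        noise = Waveform(rng.standard_normal(400) * 0.02, 8000)
        mixed = mix_at_snr(speech, noise, snr_db)
        noise_part = Waveform(mixed.samples - speech.samples, 8000)
        realized = rms_dbfs(speech) - rms_dbfs(noise_part)
        assert realized == pytest.approx(snr_db, abs=1e-9)

    def test_short_noise_rejected(self, rate):
        rng = np.random.default_rng(2)
        speech = Waveform(rng.standard_normal(1000) * 0.1, rate)
        noise = Waveform(rng.standard_normal(500) * 0.1, rate)
        with pytest.raises(ValueError, match="shorter"):
            mix_at_snr(speech, noise, 0.0)

    def test_long_noise_cropped_from_seeded_offset(self, rate):
        rng_sig = np.random.default_rng(3)
        speech = Waveform(rng_sig.standard_normal(1000) * 0.1, rate)
        noise = Waveform(rng_sig.standard_normal(5000) * 0.1, rate)
        a = mix_at_snr(speech, noise, 0.0, rng=np.random.default_rng(7))
        b = mix_at_snr(speech, noise, 0.0, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.n_samples == speech.n_samples

    def test_zero_rms_component_rejected(self, rate):
        speech = Waveform(np.zeros(100), rate)
        noise = Waveform(np.ones(100), rate)
        with pytest.raises(UndefinedLevelError):
            mix_at_snr(speech, noise, 0.0)
        with pytest.raises(UndefinedLevelError):
            mix_at_snr(noise, Waveform(np.zeros(100), rate), 0.0)

    def test_sample_rate_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample-rate"):
            mix_at_snr(Waveform(np.ones(10), 8000), Waveform(np.ones(10), 16_000), 0.0)


class TestPrependSilence:
    @pytest.mark.parametrize("rate_hz,expected_pad", [(44_100, 8820), (16_000, 3200)])
    def test_200ms_pad_length(self, rate_hz, expected_pad):
        w = Waveform(np.ones(100), rate_hz)
        out = prepend_silence(w, 200.0)
        assert out.n_samples == 100 + expected_pad
        assert np.all(out.samples[:expected_pad] == 0.0)

    def test_original_samples_bit_identical(self):
        rng = np.random.default_rng(4)
        w = Waveform(rng.standard_normal(333) * 0.2, 44_100)
        out = prepend_silence(w, 200.0)
        np.testing.assert_array_equal(out.samples[-333:], w.samples)

    def test_zero_duration_is_identity(self):
        w = Waveform(np.ones(50), 8000)
        assert prepend_silence(w, 0.0) is w

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            prepend_silence(Waveform(np.ones(10), 8000), -1.0)


class TestWavIO:
    def test_float32_round_trip(self, tmp_path, sine):
        w = sine(440.0, amplitude=0.5)
        path = tmp_path / "tone.wav"
        write_wav(path, w)
        back = read_wav(path)
        assert back.sample_rate_hz == w.sample_rate_hz
        np.testing.assert_allclose(back.samples, w.samples, atol=1e-7)

    def test_pcm16_round_trip_within_quantization(self, tmp_path, sine):
        w = sine(440.0, amplitude=0.5)
        path = tmp_path / "tone16.wav"
        write_wav(path, w, subtype="pcm16")
        back = read_wav(path)
        np.testing.assert_allclose(back.samples, w.samples, atol=1.0 / 32768)

    def test_stereo_rejected(self, tmp_path):
        from scipy.io import wavfile

        path = tmp_path / "stereo.wav"
        wavfile.write(path, 8000, np.zeros((100, 2), dtype=np.float32))
        with pytest.raises(ValueError, match="mono"):
            read_wav(path)


class TestWaveformInvariants:
    def test_rejects_empty_and_bad_rate(self):
        with pytest.raises(ValueError):
            Waveform(np.array([]), 8000)
        with pytest.raises(ValueError):
            Waveform(np.ones(10), 0)

    def test_samples_read_only(self):
        w = Waveform(np.ones(10), 8000)
        with pytest.raises(ValueError):
            w.samples[0] = 2.0
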