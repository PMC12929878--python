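"""Waveform container, level calibration, SNR mixing, and WAV I/O.

All audio in the engine is mono, real-valued, full scale ±1.0. Levels are
expressed in dB FS (decibels relative to digital full scale): a constant
signal at amplitude 1.0 has an RMS level of 0 dB FS, a full-scale sine
−3.01 dB FS. Test stimuli are conventionally calibrated to a common RMS
level (default −25 dB FS) so that a single loudness setting holds across a
whole session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import HeadroomError, UndefinedLevelError

DEFAULT_SAMPLE_RATE = 44_100
DEFAULT_TARGET_RMS_DBFS = -25.0
DEFAULT_SILENCE_PREPEND_MS = 200.0


@dataclass(frozen=True)
class Waveform:
    """Sampled mono audio with a full-scale ±1.0 convention.

    Parameters
    ----------
    samples : array-like of float
        Signal samples; full scale is ±1.0.
    sample_rate_hz : int
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"waveform must be mono (1-D), got shape {samples.shape}")
        if samples.size < 1:
            raise ValueError("waveform must contain at least one sample")
        if not (isinstance(self.sample_rate_hz, (int, np.integer)) and self.sample_rate_hz > 0):
            raise ValueError(f"sample_rate_hz must be a positive integer, got {self.sample_rate_hz!r}")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate_hz", int(self.sample_rate_hz))

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.samples)))

    def with_samples(self, samples: np.ndarray) -> "Waveform":
        return Waveform(samples, self.sample_rate_hz)


@dataclass(frozen=True)
class LevelSpec:
    """Target RMS level in dB FS; must be below full scale (negative)."""

    target_rms_dbfs: float = DEFAULT_TARGET_RMS_DBFS

    def __post_init__(self) -> None:
        if not self.target_rms_dbfs < 0:
            raise ValueError(
                f"target_rms_dbfs must be < 0 dB FS (full-scale sine is ≈ −3.01); got {self.target_rms_dbfs}"
            )


def rms_dbfs(w: Waveform) -> float:
    """RMS level of a waveform in dB FS.

    Raises :class:`UndefinedLevelError` on an all-zero signal (log of zero).
    """
    rms = float(np.sqrt(np.mean(np.square(w.samples))))
    if rms == 0.0:
        raise UndefinedLevelError("RMS level of an all-zero signal is undefined")
    return 20.0 * np.log10(rms)


def calibrate_rms(w: Waveform, spec: LevelSpec = LevelSpec()) -> Waveform:
    """Scale a waveform to an exact RMS target in dB FS.

    The waveform shape is unchanged up to a single positive gain. If the
    required gain would push the peak beyond full scale, a
    :class:`HeadroomError` is raised naming the dB reduction needed: the
    level contract is bit-exact, never a silent limiter.
    """
    current = rms_dbfs(w)
    gain = 10.0 ** ((spec.target_rms_dbfs - current) / 20.0)
    out = w.samples * gain
    peak = float(np.max(np.abs(out)))
    if peak > 1.0:
        excess_db = 20.0 * np.log10(peak)
        raise HeadroomError(
            f"calibration to {spec.target_rms_dbfs} dB FS would clip "
            f"(peak {peak:.4f} > 1.0); reduce target by at least {excess_db:.2f} dB"
        )
    return w.with_samples(out)


def mix_at_snr(speech: Waveform, noise: Waveform, snr_db: float, *, rng=None) -> Waveform:
    """Mix speech with noise at an exact component SNR.

    The speech level is held fixed and the noise is scaled, so the target
    presentation level set by calibration is preserved. The noise must be
    at least as long as the speech; longer noise is cropped from a random
    offset drawn from ``rng`` (or from the start when ``rng`` is None).

    Returns speech + g·noise with 20·log10(RMS_speech / RMS_scaled_noise)
    equal to ``snr_db`` exactly (to floating-point precision).
    """
    if speech.sample_rate_hz != noise.sample_rate_hz:
        raise ValueError(
            f"sample-rate mismatch: speech {speech.sample_rate_hz} Hz vs noise {noise.sample_rate_hz} Hz"
        )
    if noise.n_samples < speech.n_samples:
        raise ValueError(
            f"noise ({noise.n_samples} samples) shorter than speech ({speech.n_samples}); "
            "supply noise at least as long as the speech"
        )
    if noise.n_samples > speech.n_samples:
        max_offset = noise.n_samples - speech.n_samples
        offset = int(rng.integers(0, max_offset + 1)) if rng is not None else 0
        noise_seg = noise.samples[offset : offset + speech.n_samples]
    else:
        noise_seg = noise.samples

    speech_rms = float(np.sqrt(np.mean(np.square(speech.samples))))
    noise_rms = float(np.sqrt(np.mean(np.square(noise_seg))))
    if speech_rms == 0.0 or noise_rms == 0.0:
        raise UndefinedLevelError("SNR is undefined for zero-RMS speech or noise")
    gain = (speech_rms / noise_rms) * 10.0 ** (-snr_db / 20.0)
    return speech.with_samples(speech.samples + gain * noise_seg)


def prepend_silence(w: Waveform, duration_ms: float = DEFAULT_SILENCE_PREPEND_MS) -> Waveform:
    """Prepend exact digital silence (round-half-up to integer samples).

    Used before playback so that wireless-streaming wake-up delays cannot
    cut off the stimulus onset. The original samples are preserved
    bit-exactly after the pad.
    """
    if duration_ms < 0:
        raise ValueError(f"silence duration must be ≥ 0 ms, got {duration_ms}")
    n_pad = int(np.floor(duration_ms * w.sample_rate_hz / 1000.0 + 0.5))
    if n_pad == 0:
        return w
    return w.with_samples(np.concatenate([np.zeros(n_pad), w.samples]))


# ---------------------------------------------------------------------------
# WAV I/O — mono PCM16/PCM24/float32, no dithering on integer export.

def read_wav(path: str | Path) -> Waveform:
    """Read a mono WAV file into a full-scale ±1.0 waveform.

    Integer PCM is scaled by its nominal full scale (2^(bits−1)); float
    data is passed through unchanged. Stereo files are rejected.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: only mono WAV is supported, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:  # scipy loads 24-bit PCM into int32
        samples = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Waveform(samples, int(rate))


def write_wav(path: str | Path, w: Waveform, subtype: str = "float32") -> None:
    """Write a waveform to WAV (``subtype``: 'float32' or 'pcm16').

    Integer export truncates toward zero with no dither, keeping the
    round-trip deterministic.
    """
    if subtype == "float32":
        wavfile.write(str(path), w.sample_rate_hz, w.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(w.samples, -1.0, 32767.0 / 32768.0)
        wavfile.write(str(path), w.sample_rate_hz, (clipped * 32768.0).astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r} (use 'float32' or 'pcm16')")
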