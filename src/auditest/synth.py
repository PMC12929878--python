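"""Synthetic test stimuli: digit-like tokens, speech-shaped noise, and
spectro-temporal sweep ("stripes") stimuli.

Real listening studies use recorded corpora (spoken digits, sentence
material). The engine is validated offline, so this module generates
deterministic stand-ins with the spectro-temporal properties the
procedures rely on: digit tokens are distinct harmonic complexes,
speech-shaped noise matches the long-term spectrum of a reference signal,
and the sweep stimuli are sums of concurrent exponential glides whose
repetition density is the tracked difficulty variable. The sweep geometry
is a documented surrogate: it exercises the adaptive procedure and the
up/down discrimination, and makes no claim of perceptual equivalence to
any recorded stimulus set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .audio import DEFAULT_TARGET_RMS_DBFS, LevelSpec, Waveform, calibrate_rms, mix_at_snr

__all__ = [
    "DinTrialSpec",
    "StripesSpec",
    "synthesize_digit_token",
    "synthesize_speech_shaped_noise",
    "synthesize_stripes",
    "synthesize_din_trial",
    "spectrogram_orientation",
    "count_sweep_crossings",
]


@dataclass(frozen=True)
class DinTrialSpec:
    """One digits-in-noise trial: an ordered digit triple at a given SNR."""

    digits: tuple[int, int, int]
    snr_db: float
    speech_level_dbfs: float = DEFAULT_TARGET_RMS_DBFS

    def __post_init__(self) -> None:
        if len(self.digits) != 3:
            raise ValueError(f"a trial presents exactly 3 digits, got {len(self.digits)}")
        if any(not (0 <= d <= 9) for d in self.digits):
            raise ValueError(f"digits must be in 0–9, got {self.digits}")
        if not (-20.0 <= self.snr_db <= 20.0):
            raise ValueError(f"snr_db must lie in [−20, 20] dB, got {self.snr_db}")


@dataclass(frozen=True)
class StripesSpec:
    """Geometry of a sweep stimulus.

    ``density`` is the number of sweep repetitions per component over the
    stimulus duration (dimensionless, ≥ 1): higher density packs the
    spectro-temporal plane more tightly and is harder to discriminate.
    ``direction`` sets the sweep sign; up and down stimuli differ only in
    that sign.
    """

    density: float
    direction: str = "up"
    duration_s: float = 0.5
    f_low_hz: float = 250.0
    f_high_hz: float = 8000.0
    n_components: int = 4

    def __post_init__(self) -> None:
        if self.density < 1.0:
            raise ValueError(f"density must be ≥ 1.0 (at least one sweep), got {self.density}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if not (0 < self.f_low_hz < self.f_high_hz):
            raise ValueError("need 0 < f_low_hz < f_high_hz")
        if self.n_components < 1:
            raise ValueError("n_components must be ≥ 1")


# Per-digit voicing parameters: fundamental on a whole-tone-ish grid plus a
# digit-specific syllable envelope rate, enough to keep all 45 token pairs
# below 0.9 normalized cross-correlation.
_DIGIT_F0 = [96.0, 110.0, 126.0, 144.0, 165.0, 189.0, 216.0, 247.0, 283.0, 324.0]
_DIGIT_AM_HZ = [3.0, 4.5, 6.0, 7.5, 9.0, 10.5, 12.0, 13.5, 15.0, 16.5]


def _ramp(n_samples: int, rate: int, ramp_ms: float = 10.0) -> np.ndarray:
    env = np.ones(n_samples)
    n_ramp = min(int(rate * ramp_ms / 1000.0), n_samples // 2)
    if n_ramp > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] *= r
        env[-n_ramp:] *= r[::-1]
    return env


def synthesize_digit_token(
    digit: int,
    rate: int = 44_100,
    *,
    duration_s: float = 0.35,
    seed: int = 0,
    level: LevelSpec = LevelSpec(),
) -> Waveform:
    """Deterministic digit-like token: a harmonic complex with a
    digit-specific fundamental, spectral tilt, and syllabic amplitude
    modulation, calibrated to ``level``.

    Same (digit, seed, rate) always yields a bit-identical token.
    """
    if not (0 <= int(digit) <= 9) or int(digit) != digit:
        raise ValueError(f"digit must be an integer in 0–9, got {digit!r}")
    digit = int(digit)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), digit]))
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    f0 = _DIGIT_F0[digit]
    n_harm = int(min(20, (0.45 * rate) // f0))
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    # spectral tilt alternates sign with digit parity to separate neighbours
    tilt = -6.0 if digit % 2 == 0 else -3.0
    x = np.zeros(n)
    for h in range(1, n_harm + 1):
        amp = 10.0 ** (tilt * np.log2(h) / 20.0)
        x += amp * np.sin(2 * np.pi * h * f0 * t + phases[h - 1])
    am = 1.0 + 0.6 * np.sin(2 * np.pi * _DIGIT_AM_HZ[digit] * t)
    x *= am * _ramp(n, rate)
    return calibrate_rms(Waveform(x / (np.max(np.abs(x)) * 1.5), rate), level)


def synthesize_speech_shaped_noise(
    reference: Waveform, duration_s: float, seed: int = 0
) -> Waveform:
    """Stationary Gaussian noise spectrally shaped to a reference signal.

    White Gaussian noise is filtered in the frequency domain by the square
    root of the reference's Welch power spectrum (its long-term average
    spectrum), then scaled to the reference RMS. The result is stationary:
    the RMS of any 250 ms window stays within a few dB of the global RMS.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rate = reference.sample_rate_hz
    n = int(round(duration_s * rate))
    nperseg = min(1024, reference.n_samples)
    freqs, psd = sps.welch(reference.samples, fs=rate, nperseg=nperseg)
    if not np.any(psd > 0):
        raise ValueError("reference signal has no energy to shape to")
    amp_ref = np.sqrt(psd)

    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    bin_freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.interp(bin_freqs, freqs, amp_ref)
    shaped = np.fft.irfft(spec * shape, n=n)

    ref_rms = np.sqrt(np.mean(reference.samples**2))
    shaped *= ref_rms / np.sqrt(np.mean(shaped**2))
    return Waveform(shaped, rate)


def synthesize_stripes(spec: StripesSpec, rate: int = 44_100, seed: int = 0) -> Waveform:
    """Sum of concurrent exponential frequency sweeps.

    Each of ``n_components`` glides repeatedly traverses
    [f_low, f_high] on a log-frequency axis, ``density`` times over the
    stimulus, with components evenly staggered in sweep phase. ``up``
    sweeps rise in frequency, ``down`` sweeps fall; the two are mirror
    images of one another on the spectrogram. The overall level is
    calibrated to the engine's standard −25 dB FS.
    """
    if spec.f_high_hz >= rate / 2:
        raise ValueError(
            f"f_high_hz {spec.f_high_hz} must be below Nyquist ({rate / 2} Hz at {rate} Hz)"
        )
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * rate))
    t = np.arange(n) / rate
    log_ratio = np.log(spec.f_high_hz / spec.f_low_hz)
    x = np.zeros(n)
    for k in range(spec.n_components):
        u = np.mod(spec.density * t / spec.duration_s + k / spec.n_components, 1.0)
        if spec.direction == "down":
            u = 1.0 - u
        inst_freq = spec.f_low_hz * np.exp(log_ratio * u)
        phase = 2 * np.pi * np.cumsum(inst_freq) / rate + rng.uniform(0, 2 * np.pi)
        x += np.sin(phase)
    x *= _ramp(n, rate)
    return calibrate_rms(Waveform(x / (np.max(np.abs(x)) * 1.2), rate), LevelSpec())


def spectrogram_orientation(w: Waveform, nperseg: int = 256) -> float:
    """Sweep-orientation statistic: positive for upward sweeps, negative
    for downward.

    The log-spectrogram's 2-D spectrum concentrates energy on lines
    orthogonal to the ridge direction, so the normalized energy
    difference between the opposite-sign and same-sign quadrants of the
    (spectral frequency × temporal frequency) plane gives the sign of
    the dominant ridge slope regardless of how many concurrent sweeps
    are present. Statistic lies in [−1, 1].
    """
    _, _, S = sps.spectrogram(
        w.samples, fs=w.sample_rate_hz, nperseg=nperseg, noverlap=3 * nperseg // 4
    )
    L = np.log(S + 1e-12)
    L = L - L.mean()
    F = np.abs(np.fft.fft2(L)) ** 2
    kf = np.fft.fftfreq(F.shape[0])[:, None]
    kt = np.fft.fftfreq(F.shape[1])[None, :]
    opp = F[kf * kt < 0].sum()
    same = F[kf * kt > 0].sum()
    return float((opp - same) / (opp + same))


def count_sweep_crossings(w: Waveform, freq_hz: float, nperseg: int = 256) -> int:
    """Count crossings of a fixed frequency by the dominant spectrogram
    ridge — a sweep-repetition counter for single-component stimuli
    (each sweep traversal crosses the mid frequency)."""
    f, _, S = sps.spectrogram(
        w.samples, fs=w.sample_rate_hz, nperseg=nperseg, noverlap=3 * nperseg // 4
    )
    ridge = f[np.argmax(S, axis=0)]
    above = (ridge > freq_hz).astype(int)
    return int(np.sum(np.abs(np.diff(above))))


def synthesize_din_trial(
    trial: DinTrialSpec,
    rate: int = 44_100,
    seed: int = 0,
    *,
    gap_s: float = 0.15,
    noise_pad_s: float = 0.2,
) -> Waveform:
    """Assemble a full digits-in-noise trial waveform.

    Concatenates the three digit tokens with short gaps, calibrates the
    speech to ``trial.speech_level_dbfs``, and mixes in speech-shaped
    stationary noise at ``trial.snr_db`` (noise scaled, speech fixed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 977]))
    gap = np.zeros(int(round(gap_s * rate)))
    parts: list[np.ndarray] = []
    for i, d in enumerate(trial.digits):
        tok = synthesize_digit_token(d, rate, seed=seed)
        parts.append(tok.samples)
        if i < 2:
            parts.append(gap)
    speech = calibrate_rms(
        Waveform(np.concatenate(parts), rate), LevelSpec(trial.speech_level_dbfs)
    )
    noise = synthesize_speech_shaped_noise(
        speech, speech.duration_s + noise_pad_s, seed=seed + 1
    )
    return mix_at_snr(speech, noise, trial.snr_db, rng=rng)
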