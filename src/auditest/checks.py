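"""Technical checks: loudness, microphone, and the connection check.

The connection check decides whether a stimulus reached the listener over
a direct audio connection (streaming/headphones) or leaked out of the
device loudspeakers. During a playback a concurrent microphone recording
is taken; the engine then compares recording and playback by (a) the peak
normalized cross-correlation in the temporal domain over a bounded lag
window and (b) the Pearson correlation of their smoothed amplitude
spectra after best-lag alignment. A high correlation in *either* domain
means the recording matches the playback — i.e., the sound came out of
the loudspeakers — so a match is a FAIL for this check. The verdict is
advisory: it informs participant and experimenter but does not block a
session.

The companion :func:`simulate_leak_scene` generates synthetic acoustic
scenes (delayed, filtered, attenuated playback plus background noise) so
the detector can be exercised and calibrated without hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .audio import Waveform, rms_dbfs
from .errors import HeadroomError

__all__ = [
    "ConnectionCheckConfig",
    "CheckResult",
    "connection_check",
    "simulate_leak_scene",
    "LoudnessSession",
    "loudness_check",
    "microphone_check",
]


@dataclass(frozen=True)
class CheckResult:
    """Outcome of a technical check: verdict, named metrics, advisory text."""

    passed: bool
    metrics: dict = field(default_factory=dict)
    advisory: str = ""


@dataclass(frozen=True)
class ConnectionCheckConfig:
    """Detector thresholds, calibrated on the synthetic scene grid to
    ≥95% leak detection at leak-to-noise ≥ 10 dB with ≤5% false alarms
    on independent noise; all exposed for re-tuning to other hardware."""

    xcorr_threshold: float = 0.3
    spectral_corr_threshold: float = 0.6
    max_lag_ms: float = 250.0
    spectrum_smoothing_bins: int = 9

    def __post_init__(self) -> None:
        if not (0 < self.xcorr_threshold <= 1 and 0 < self.spectral_corr_threshold <= 1):
            raise ValueError("correlation thresholds must lie in (0, 1]")
        if self.max_lag_ms < 0:
            raise ValueError("max_lag_ms must be ≥ 0")
        if self.spectrum_smoothing_bins < 1:
            raise ValueError("spectrum_smoothing_bins must be ≥ 1")


def _smooth(spectrum: np.ndarray, bins: int) -> np.ndarray:
    if bins <= 1:
        return spectrum
    kernel = np.ones(bins) / bins
    return np.convolve(spectrum, kernel, mode="same")


def connection_check(
    playback: Waveform, recording: Waveform, cfg: ConnectionCheckConfig = ConnectionCheckConfig()
) -> CheckResult:
    """Compare a recording against the played-back stimulus.

    Reports ``peak_xcorr`` (peak |normalized cross-correlation| over lags
    0..max_lag_ms), ``spectral_corr`` (Pearson correlation of smoothed
    amplitude spectra at the best lag) and ``best_lag_ms``. The check
    FAILS — a loudspeaker leak was detected — when either metric reaches
    its threshold; both metrics are invariant to the recording's overall
    level and polarity. A zero-energy recording yields an inconclusive
    non-pass with a silent-microphone advisory.
    """
    if playback.sample_rate_hz != recording.sample_rate_hz:
        raise ValueError("playback and recording must share a sample rate")
    if recording.n_samples < playback.n_samples:
        raise ValueError("recording must be at least as long as the playback")

    p = playback.samples
    r = recording.samples
    if not np.any(r != 0.0):
        return CheckResult(
            passed=False,
            metrics={"peak_xcorr": float("nan"), "spectral_corr": float("nan"), "best_lag_ms": float("nan")},
            advisory="inconclusive: the recording is digital silence (microphone muted or disconnected?)",
        )

    rate = playback.sample_rate_hz
    n = p.size
    max_lag = min(int(round(cfg.max_lag_ms * rate / 1000.0)), r.size - n)

    # numerator at every lag where the playback fits entirely in the recording
    num = sps.correlate(r, p, mode="valid")[: max_lag + 1]
    # sliding recording energy over the same windows, via cumulative sums
    csum = np.concatenate([[0.0], np.cumsum(r * r)])
    window_energy = csum[n : n + max_lag + 1] - csum[: max_lag + 1]
    p_energy = float(np.sum(p * p))
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = num / np.sqrt(p_energy * window_energy)
    ncc = np.nan_to_num(ncc, nan=0.0, posinf=0.0, neginf=0.0)
    best = int(np.argmax(np.abs(ncc)))
    peak_xcorr = float(abs(ncc[best]))
    best_lag_ms = 1000.0 * best / rate

    # amplitude spectra on matched-length segments after best-lag alignment,
    # so pure delay does not depress the spectral metric
    seg = r[best : best + n]
    spec_p = _smooth(np.abs(np.fft.rfft(p)), cfg.spectrum_smoothing_bins)
    spec_r = _smooth(np.abs(np.fft.rfft(seg)), cfg.spectrum_smoothing_bins)
    if np.std(spec_p) == 0.0 or np.std(spec_r) == 0.0:
        spectral_corr = 0.0
    else:
        spectral_corr = float(np.corrcoef(spec_p, spec_r)[0, 1])

    match = peak_xcorr >= cfg.xcorr_threshold or spectral_corr >= cfg.spectral_corr_threshold
    advisory = (
        "recording matches the playback: stimulus likely played over loudspeakers, "
        "not a direct audio connection"
        if match
        else "recording does not match the playback: direct audio connection likely"
    )
    return CheckResult(
        passed=not match,
        metrics={"peak_xcorr": peak_xcorr, "spectral_corr": spectral_corr, "best_lag_ms": best_lag_ms},
        advisory=advisory,
    )


def simulate_leak_scene(
    playback: Waveform,
    leak_gain_db: float,
    delay_ms: float = 0.0,
    filter_spec: tuple[str, float] | None = None,
    noise_level_dbfs: float | None = None,
    seed: int = 0,
    tail_s: float = 0.1,
) -> Waveform:
    """Synthetic microphone recording of a playback scene.

    The loudspeaker path is modelled as delay + optional Butterworth
    filter (``filter_spec = (kind, cutoff_hz)``, kind 'lowpass' or
    'highpass') + amplitude gain ``leak_gain_db``; stationary Gaussian
    background noise is added at ``noise_level_dbfs`` RMS. With
    ``leak_gain_db = −inf`` the recording is noise only — the
    direct-audio scenario the connection check should pass.
    """
    if delay_ms < 0:
        raise ValueError("delay_ms must be ≥ 0")
    rate = playback.sample_rate_hz
    rng = np.random.default_rng(seed)
    n_delay = int(round(delay_ms * rate / 1000.0))
    n_out = playback.n_samples + n_delay + int(round(tail_s * rate))

    out = np.zeros(n_out)
    if np.isfinite(leak_gain_db):
        leaked = playback.samples
        if filter_spec is not None:
            kind, cutoff_hz = filter_spec
            sos = sps.butter(4, cutoff_hz, btype=kind, fs=rate, output="sos")
            leaked = sps.sosfilt(sos, leaked)
        out[n_delay : n_delay + leaked.size] += 10.0 ** (leak_gain_db / 20.0) * leaked
    if noise_level_dbfs is not None:
        out += 10.0 ** (noise_level_dbfs / 20.0) * rng.standard_normal(n_out)
    return Waveform(out, rate)


class LoudnessSession:
    """Comfort-level loudness setting for one session.

    The participant sets a playback gain against a probe stimulus
    calibrated like the task material; once accepted the gain is locked
    for the rest of the session (participants are asked not to change
    their presentation level afterwards).
    """

    def __init__(self) -> None:
        self.gain_db: float | None = None

    @property
    def locked(self) -> bool:
        return self.gain_db is not None

    def set_gain(self, probe: Waveform, chosen_gain_db: float) -> CheckResult:
        if self.locked:
            raise RuntimeError(
                f"loudness already set to {self.gain_db} dB for this session; "
                "the presentation level is locked after the loudness check"
            )
        peak_after = probe.peak * 10.0 ** (chosen_gain_db / 20.0)
        if peak_after > 1.0:
            return CheckResult(
                passed=False,
                metrics={"chosen_gain_db": chosen_gain_db, "peak_after_gain": peak_after},
                advisory=(
                    f"gain of {chosen_gain_db:+.1f} dB would clip the probe "
                    f"(peak {peak_after:.3f} > 1.0); choose a lower level"
                ),
            )
        self.gain_db = float(chosen_gain_db)
        return CheckResult(
            passed=True,
            metrics={"chosen_gain_db": chosen_gain_db, "peak_after_gain": peak_after},
            advisory="comfort level recorded; please do not change your device volume",
        )


def loudness_check(probe: Waveform, chosen_gain_db: float, session: LoudnessSession | None = None) -> CheckResult:
    """Functional wrapper over :class:`LoudnessSession.set_gain`."""
    if session is None:
        session = LoudnessSession()
    return session.set_gain(probe, chosen_gain_db)


def microphone_check(
    recorded: Waveform,
    arm_delay_ms: float = 500.0,
    max_duration_s: float | None = None,
    silence_floor_dbfs: float = -60.0,
) -> CheckResult:
    """Validate that a vocal-response recording contains signal.

    Passes when the recorded energy exceeds the silence floor within
    ``max_duration_s`` (longer recordings are truncated at the cap, noted
    in the metrics). ``arm_delay_ms`` is the visual delay applied by the
    session runner before capture goes live — reported in the metrics so
    it lands in session metadata.
    """
    samples = recorded.samples
    truncated = False
    if max_duration_s is not None:
        cap = int(round(max_duration_s * recorded.sample_rate_hz))
        if samples.size > cap:
            samples = samples[:cap]
            truncated = True
    metrics = {
        "arm_delay_ms": arm_delay_ms,
        "duration_s": samples.size / recorded.sample_rate_hz,
        "truncated": float(truncated),
    }
    if not np.any(samples != 0.0):
        metrics["rms_dbfs"] = float("-inf")
        return CheckResult(
            passed=False, metrics=metrics,
            advisory="no signal recorded (digital silence); check the microphone and retry",
        )
    level = rms_dbfs(Waveform(samples, recorded.sample_rate_hz))
    metrics["rms_dbfs"] = level
    if level <= silence_floor_dbfs:
        return CheckResult(
            passed=False, metrics=metrics,
            advisory=f"recorded level {level:.1f} dB FS is below the {silence_floor_dbfs:.0f} dB FS floor; retry",
        )
    return CheckResult(passed=True, metrics=metrics, advisory="microphone working")
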