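"""Shared fixtures and independent oracles.

``brute_force_trace`` is a deliberately plain re-implementation of the
transformed up–down rule (explicit counters, no shared code with the
engine) used to check the staircase trajectory bit-for-bit.
"""

from __future__ import annotations

import numpy as np
import pytest

from auditest import LevelSpec, Waveform, calibrate_rms


@pytest.fixture
def rate() -> int:
    return 16_000  # cheap but high enough for every synthesis check


@pytest.fixture
def sine(rate):
    def make(freq_hz: float = 1000.0, duration_s: float = 0.5, amplitude: float = 1.0) -> Waveform:
        n_cycles = max(1, round(freq_hz * duration_s))
        n = int(round(n_cycles * rate / freq_hz))  # integer number of cycles
        t = np.arange(n) / rate
        return Waveform(amplitude * np.sin(2 * np.pi * freq_hz * t), rate)

    return make


@pytest.fixture
def calibrated_chirp(rate):
    """Broadband probe at −25 dB FS, the standard stimulus level."""
    from scipy.signal import chirp

    t = np.arange(int(0.5 * rate)) / rate
    return calibrate_rms(Waveform(chirp(t, 300, 0.5, 6000), rate), LevelSpec(-25.0))


def brute_force_trace(
    responses,
    *,
    n_up: int,
    n_down: int,
    schedule,
    start: float,
    lo: float,
    hi: float,
    harder: int,
    stop_trials=None,
    stop_reversals=None,
    max_trials=None,
):
    """Independent trace simulator: returns (presented_levels, reversals).

    ``reversals`` is a list of (0-based trial index, level). Stops at the
    stop rule or when responses run out.
    """
    level = float(start)
    up_count = 0
    down_count = 0
    prev_direction = None
    levels = []
    reversals = []
    for i, correct in enumerate(responses):
        levels.append(level)
        if correct:
            up_count += 1
            down_count = 0
        else:
            down_count += 1
            up_count = 0
        direction = None
        if correct and up_count >= n_up:
            direction = "harder"
        elif (not correct) and down_count >= n_down:
            direction = "easier"
        if direction is not None:
            if prev_direction is not None and direction != prev_direction:
                reversals.append((i, level))
            step = None
            for threshold, size in schedule:
                if len(reversals) >= threshold:
                    step = size
            delta = step * harder if direction == "harder" else -step * harder
            level = min(max(level + delta, lo), hi)
            prev_direction = direction
            up_count = 0
            down_count = 0
        n_trials = i + 1
        if stop_trials is not None and n_trials >= stop_trials:
            break
        if stop_reversals is not None and len(reversals) >= stop_reversals:
            break
        if max_trials is not None and n_trials >= max_trials:
            break
    return levels, reversals
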