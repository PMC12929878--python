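"""Transformed up–down adaptive tracking.

The engine moves a tracked stimulus variable (SNR in dB for
digits-in-noise, sweep density for the spectro-temporal test) harder after
``n_up`` consecutive correct responses and easier after ``n_down``
consecutive incorrect ones. A reversal is a trial at which the intended
direction of movement flips; thresholds are estimated either from the
presented levels of the final trials (digits-in-noise convention) or from
the mean of the final reversals.

Classical convergence points: a 1-up-1-down track oscillates around the
50%-correct level, a 2-up-1-down track around the 70.7%-correct level
(the level where P(two consecutive correct) = 1/2).

Semantics at the level rails: a step that is clamped by ``min_level`` /
``max_level`` still counts as a move in its intended direction, so a
reversal is logged only when the *intended* direction flips — sitting on a
rail for several trials logs nothing.

Step schedule: each move uses the step size associated with the number of
reversals logged at that moment, counting a reversal logged by the move
itself. With the schedule ``[(0, 0.5), (4, 0.2)]`` the move that creates
the fourth reversal (and every later move until the next schedule
threshold) steps by 0.2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import StaircaseError

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "din_config",
    "stripes_config",
    "new_state",
    "update",
    "run_sequence",
    "estimate_srt_final_trials",
    "estimate_threshold_reversal_mean",
    "combine_runs",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of a transformed up–down track.

    Parameters
    ----------
    n_up : int
        Consecutive correct responses required before the task is made
        harder ("1-up" / "2-up" in procedure names).
    n_down : int
        Consecutive incorrect responses before the task is made easier
        (1 in both standard procedures here).
    step_schedule : list of (reversal_count, step_size)
        Step size in tracked units as a function of reversals logged;
        thresholds strictly increasing, first entry at 0.
    start_level, min_level, max_level : float
        Starting value and rails of the tracked variable.
    stop_total_trials : int or None
        Finish after exactly this many trials.
    stop_total_reversals : int or None
        Finish once this many reversals are logged.
    max_trials : int or None
        Safety cap: finish (unconverged) after this many trials even if
        the reversal criterion has not been met.
    harder_direction : {+1, -1}
        Sign applied to the tracked variable when the task gets harder
        (−1 for SNR tracks, +1 for density tracks).
    """

    n_up: int
    n_down: int
    step_schedule: tuple[tuple[int, float], ...]
    start_level: float
    min_level: float
    max_level: float
    stop_total_trials: int | None = None
    stop_total_reversals: int | None = None
    max_trials: int | None = None
    harder_direction: int = -1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "step_schedule", tuple((int(r), float(s)) for r, s in self.step_schedule)
        )
        if self.n_up < 1 or self.n_down < 1:
            raise ValueError("n_up and n_down must be positive integers")
        if not self.step_schedule:
            raise ValueError("step_schedule must contain at least one (reversals, step) entry")
        if self.step_schedule[0][0] != 0:
            raise ValueError("step_schedule must start at reversal count 0")
        thresholds = [r for r, _ in self.step_schedule]
        if thresholds != sorted(set(thresholds)):
            raise ValueError("step_schedule thresholds must be strictly increasing")
        if any(s <= 0 for _, s in self.step_schedule):
            raise ValueError("step sizes must be > 0")
        if not (self.min_level <= self.start_level <= self.max_level):
            raise ValueError(
                f"need min_level ≤ start_level ≤ max_level, got "
                f"{self.min_level}, {self.start_level}, {self.max_level}"
            )
        if self.harder_direction not in (-1, 1):
            raise ValueError("harder_direction must be +1 or −1")
        if self.stop_total_trials is None and self.stop_total_reversals is None:
            raise ValueError("a stop rule is required (total trials and/or total reversals)")

    def step_for(self, n_reversals: int) -> float:
        """Step size in effect when ``n_reversals`` have been logged."""
        step = self.step_schedule[0][1]
        for threshold, size in self.step_schedule:
            if n_reversals >= threshold:
                step = size
        return step

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_up": self.n_up,
            "n_down": self.n_down,
            "step_schedule": [list(pair) for pair in self.step_schedule],
            "start_level": self.start_level,
            "min_level": self.min_level,
            "max_level": self.max_level,
            "stop_total_trials": self.stop_total_trials,
            "stop_total_reversals": self.stop_total_reversals,
            "max_trials": self.max_trials,
            "harder_direction": self.harder_direction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StaircaseConfig":
        d = dict(d)
        d["step_schedule"] = tuple(tuple(pair) for pair in d["step_schedule"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StaircaseConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def din_config(
    *,
    step_db: float = 2.0,
    start_db: float = 0.0,
    min_db: float = -20.0,
    max_db: float = 20.0,
    n_trials: int = 24,
) -> StaircaseConfig:
    """Standard digits-in-noise track: 1-up-1-down, 2 dB steps, SNR from
    0 dB within ±20 dB, 24 trials, lower SNR = harder."""
    return StaircaseConfig(
        n_up=1,
        n_down=1,
        step_schedule=((0, step_db),),
        start_level=start_db,
        min_level=min_db,
        max_level=max_db,
        stop_total_trials=n_trials,
        harder_direction=-1,
    )


def stripes_config(
    *,
    start_density: float = 1.1,
    min_density: float = 1.0,
    max_density: float = 20.0,
    n_reversals: int = 8,
    max_trials: int | None = None,
) -> StaircaseConfig:
    """Standard sweep-density track: 2-up-1-down, density from 1.1, step
    0.5 for the first four reversals then 0.2 for the final four of
    eight, higher density = harder."""
    return StaircaseConfig(
        n_up=2,
        n_down=1,
        step_schedule=((0, 0.5), (4, 0.2)),
        start_level=start_density,
        min_level=min_density,
        max_level=max_density,
        stop_total_reversals=n_reversals,
        max_trials=max_trials,
        harder_direction=+1,
    )


@dataclass(frozen=True)
class StaircaseState:
    """Immutable snapshot of an adaptive track.

    ``trial_log`` holds (presented_level, correct) per trial;
    ``reversals`` holds (trial_index, level) with 0-based trial indices.
    """

    current_level: float
    trial_log: tuple[tuple[float, bool], ...] = ()
    reversals: tuple[tuple[int, float], ...] = ()
    consecutive_correct: int = 0
    consecutive_incorrect: int = 0
    last_move_direction: int = 0  # +1 harder, −1 easier, 0 no move yet
    finished: bool = False
    converged: bool = True

    @property
    def n_trials(self) -> int:
        return len(self.trial_log)

    @property
    def presented_levels(self) -> tuple[float, ...]:
        return tuple(level for level, _ in self.trial_log)


def new_state(cfg: StaircaseConfig) -> StaircaseState:
    return StaircaseState(current_level=cfg.start_level)


def update(state: StaircaseState, cfg: StaircaseConfig, correct: bool) -> StaircaseState:
    """Process one response and return the next track state.

    The response is scored against the level currently presented
    (``state.current_level``); the returned state carries the level for
    the next trial, any newly logged reversal, and the finished flag.
    """
    if state.finished:
        raise StaircaseError("cannot update a finished staircase")

    presented = state.current_level
    trial_index = len(state.trial_log)
    trial_log = state.trial_log + ((presented, bool(correct)),)

    cc = state.consecutive_correct
    ci = state.consecutive_incorrect
    move = 0  # +1 harder, −1 easier
    if correct:
        cc += 1
        ci = 0
        if cc >= cfg.n_up:
            move = +1
    else:
        ci += 1
        cc = 0
        if ci >= cfg.n_down:
            move = -1

    reversals = state.reversals
    level = presented
    last_dir = state.last_move_direction
    if move != 0:
        if last_dir != 0 and move != last_dir:
            reversals = reversals + ((trial_index, presented),)
        step = cfg.step_for(len(reversals))
        level = presented + move * cfg.harder_direction * step
        level = min(max(level, cfg.min_level), cfg.max_level)
        last_dir = move
        cc = 0
        ci = 0

    finished = False
    converged = True
    if cfg.stop_total_trials is not None and len(trial_log) >= cfg.stop_total_trials:
        finished = True
    if cfg.stop_total_reversals is not None:
        if len(reversals) >= cfg.stop_total_reversals:
            finished = True
        elif cfg.max_trials is not None and len(trial_log) >= cfg.max_trials:
            finished = True
            converged = False
    elif cfg.max_trials is not None and len(trial_log) >= cfg.max_trials:
        finished = True

    return StaircaseState(
        current_level=level,
        trial_log=trial_log,
        reversals=reversals,
        consecutive_correct=cc,
        consecutive_incorrect=ci,
        last_move_direction=last_dir,
        finished=finished,
        converged=converged,
    )


def run_sequence(cfg: StaircaseConfig, responses) -> StaircaseState:
    """Drive a fresh track through a response sequence, stopping at the
    stop rule or when the responses run out."""
    state = new_state(cfg)
    for correct in responses:
        state = update(state, cfg, correct)
        if state.finished:
            break
    return state


def estimate_srt_final_trials(
    state: StaircaseState, discard_first: int = 8, use_last: int = 16
) -> float:
    """Speech reception threshold: mean presented SNR of the final trials
    after discarding the initial ones (default: discard 8, average 16 of
    a 24-trial track)."""
    expected = discard_first + use_last
    if state.n_trials != expected:
        raise StaircaseError(
            f"SRT rule needs exactly {expected} trials "
            f"({discard_first} discarded + {use_last} averaged); track has {state.n_trials}"
        )
    levels = state.presented_levels[discard_first:]
    return sum(levels) / use_last


def estimate_threshold_reversal_mean(state: StaircaseState, n_last: int = 4) -> float:
    """Threshold as the arithmetic mean of the last ``n_last`` reversal
    levels (default: final four of an eight-reversal track)."""
    if not state.finished:
        raise StaircaseError("threshold is estimated on a finished track")
    if len(state.reversals) < n_last:
        raise StaircaseError(
            f"need at least {n_last} reversals, track has {len(state.reversals)}"
        )
    last = state.reversals[-n_last:]
    return sum(level for _, level in last) / n_last


def combine_runs(thresholds) -> float:
    """Final score across repeated runs: the arithmetic mean."""
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("combine_runs needs at least one run threshold")
    return sum(thresholds) / len(thresholds)
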