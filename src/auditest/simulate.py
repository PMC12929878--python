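"""Simulated listeners and the end-to-end validation harness.

A simulated listener answers each trial with probability

    P(correct | level) = γ + (1 − γ − λ) · Φ(±(level − μ)/σ)

— a cumulative-Gaussian psychometric function with guess rate γ, lapse
rate λ, threshold μ (the 50% point of the scaled function) and slope σ;
the sign is set by whether the task gets easier at high or at low levels.
Driving the adaptive procedures with such listeners validates the whole
engine without human participants: a 1-up-1-down track should converge
on the listener's 50%-correct level and a 2-up-1-down track on its
70.7%-correct level (the classical transformed up–down targets), and the
simulation reports the empirical bias against exactly those points.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .scoring import ScoreSummary, aggregate_keyword_list
from .staircase import (
    StaircaseConfig,
    combine_runs,
    din_config,
    estimate_srt_final_trials,
    estimate_threshold_reversal_mean,
    new_state,
    stripes_config,
    update,
)

__all__ = [
    "PsychometricListener",
    "SimulationReport",
    "respond",
    "run_staircase_with_listener",
    "run_din_simulation",
    "run_stripes_simulation",
    "run_keyword_simulation",
]

P_1UP1DOWN = 0.5
P_2UP1DOWN = float(np.sqrt(0.5))  # ≈ 0.7071: P(two consecutive correct) = 1/2


@dataclass(frozen=True)
class PsychometricListener:
    """Cumulative-Gaussian simulated listener."""

    threshold_mu: float
    slope_sigma: float
    guess_rate_gamma: float = 0.0
    lapse_rate_lambda: float = 0.0
    orientation: str = "easier_at_high"

    def __post_init__(self) -> None:
        if self.slope_sigma <= 0:
            raise ValueError("slope_sigma must be > 0")
        if not (0 <= self.guess_rate_gamma < 1):
            raise ValueError("guess_rate_gamma must lie in [0, 1)")
        if not (0 <= self.lapse_rate_lambda <= 0.1):
            raise ValueError("lapse_rate_lambda must lie in [0, 0.1]")
        if self.orientation not in ("easier_at_high", "easier_at_low"):
            raise ValueError("orientation must be 'easier_at_high' or 'easier_at_low'")

    def p_correct(self, level: float) -> float:
        z = (level - self.threshold_mu) / self.slope_sigma
        if self.orientation == "easier_at_low":
            z = -z
        return self.guess_rate_gamma + (1.0 - self.guess_rate_gamma - self.lapse_rate_lambda) * norm.cdf(z)

    def level_at_p(self, p: float) -> float:
        """Level at which P(correct) = p (inverse psychometric function)."""
        scale = 1.0 - self.guess_rate_gamma - self.lapse_rate_lambda
        q = (p - self.guess_rate_gamma) / scale
        if not (0 < q < 1):
            raise ValueError(f"p={p} is outside the listener's response range")
        z = norm.ppf(q)
        if self.orientation == "easier_at_low":
            z = -z
        return self.threshold_mu + self.slope_sigma * z

    def to_dict(self) -> dict:
        return {
            "threshold_mu": self.threshold_mu,
            "slope_sigma": self.slope_sigma,
            "guess_rate_gamma": self.guess_rate_gamma,
            "lapse_rate_lambda": self.lapse_rate_lambda,
            "orientation": self.orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PsychometricListener":
        return cls(**d)


def respond(listener: PsychometricListener, level: float, rng: np.random.Generator) -> bool:
    """One Bernoulli response at the given level (seed-reproducible)."""
    return bool(rng.random() < listener.p_correct(level))


@dataclass(frozen=True)
class SimulationReport:
    """Per-run threshold estimates and their bias against the
    procedure's theoretical convergence point."""

    estimates: tuple[float, ...]
    target: float
    n_runs: int
    seed: int
    n_unconverged: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.estimates))

    @property
    def sd(self) -> float:
        return float(np.std(self.estimates, ddof=1)) if len(self.estimates) > 1 else 0.0

    @property
    def bias(self) -> float:
        return self.mean - self.target


def run_staircase_with_listener(
    cfg: StaircaseConfig, listener: PsychometricListener, rng: np.random.Generator
):
    """Drive one adaptive track to completion with a simulated listener."""
    state = new_state(cfg)
    while not state.finished:
        state = update(state, cfg, respond(listener, state.current_level, rng))
    return state


def run_din_simulation(
    listener: PsychometricListener,
    n_runs: int = 500,
    seed: int = 0,
    cfg: StaircaseConfig | None = None,
) -> SimulationReport:
    """Monte-Carlo validation of the digits-in-noise procedure.

    Each run is a full 24-trial 1-up-1-down track; the speech reception
    threshold is the mean SNR of the final 16 trials. Bias is reported
    against the listener's 50%-correct SNR, the 1-up-1-down convergence
    point.
    """
    cfg = cfg or din_config()
    estimates = []
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), run]))
        state = run_staircase_with_listener(cfg, listener, rng)
        estimates.append(estimate_srt_final_trials(state))
    return SimulationReport(
        estimates=tuple(estimates), target=listener.level_at_p(P_1UP1DOWN), n_runs=n_runs, seed=seed
    )


def run_stripes_simulation(
    listener: PsychometricListener,
    n_sessions: int = 500,
    seed: int = 0,
    cfg: StaircaseConfig | None = None,
    runs_per_session: int = 2,
) -> SimulationReport:
    """Monte-Carlo validation of the sweep-density procedure.

    Each session runs the 2-up-1-down track ``runs_per_session`` times
    (the test is run twice and the final score is the mean of the two
    run thresholds); each run's threshold is the mean of its final four
    reversal densities. Bias is reported against the listener's
    70.7%-correct density, the 2-up-1-down convergence point. Tracks that
    hit the safety trial cap before logging all reversals are counted in
    ``n_unconverged`` and excluded from the estimates.
    """
    cfg = cfg or stripes_config(max_trials=1000)
    estimates = []
    n_unconverged = 0
    for session in range(n_sessions):
        run_thresholds = []
        for run in range(runs_per_session):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), session, run]))
            state = run_staircase_with_listener(cfg, listener, rng)
            if not state.converged:
                n_unconverged += 1
                continue
            run_thresholds.append(estimate_threshold_reversal_mean(state))
        if run_thresholds:
            estimates.append(combine_runs(run_thresholds))
    return SimulationReport(
        estimates=tuple(estimates),
        target=listener.level_at_p(P_2UP1DOWN),
        n_runs=n_sessions,
        seed=seed,
        n_unconverged=n_unconverged,
    )


def run_keyword_simulation(
    intelligibility_map: dict,
    n_lists: int = 1,
    seed: int = 0,
    n_trials: int = 15,
    keywords_per_trial: int = 3,
) -> list[ScoreSummary]:
    """Simulate keyword scoring of sentence lists.

    ``intelligibility_map`` assigns each condition a per-keyword
    recognition probability; each list is ``n_trials`` sentences of
    ``keywords_per_trial`` independent keyword draws, so the expected
    percent correct per condition is 100·p.
    """
    for cond, p in intelligibility_map.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"recognition probability for {cond!r} must lie in [0, 1], got {p}")
    summaries = []
    for cond, p in intelligibility_map.items():
        for run in range(n_lists):
            cond_key = zlib.crc32(str(cond).encode("utf-8"))
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), cond_key, run]))
            scores = rng.binomial(keywords_per_trial, p, size=n_trials)
            summaries.append(
                ScoreSummary(
                    condition=cond,
                    run=run,
                    n_trials=n_trials,
                    per_trial=tuple(int(s) for s in scores),
                    percent_correct=aggregate_keyword_list(scores, keywords_per_trial),
                )
            )
    return summaries
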