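"""Task structures and session sequencing.

Three task structures wrap stimuli into runnable sessions:

* **ordered** — a list of stimuli presented in fixed order, in seeded
  random order, or adaptively (the next file is the manifest row whose
  difficulty level matches the staircase's current level);
* **paired** — paired comparisons across two stimulus sets (cross
  product by default, all within-set pairs behind a flag);
* **ranked** — a full rank order obtained from paired comparisons by
  binary insertion: each new stimulus is compared against the midpoint
  of its remaining insertion interval, so ranking n items never needs
  more than Σ_{k=2..n} ceil(log2 k) comparisons.

The session state machine adds practice/phase sequencing and two
inactivity limits: a warning after ``warn_after_s`` without a response
and termination after ``terminate_after_s``, with all recorded trials
preserved on termination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .session_io import ManifestRow, StimulusManifest

__all__ = [
    "PhaseSpec",
    "TaskSpec",
    "InactivityPolicy",
    "RankingState",
    "ordered_next_stimulus",
    "paired_comparisons",
    "new_ranking",
    "ranking_next_comparison",
    "ranking_record_outcome",
    "Session",
    "advance_session",
]

STRUCTURES = ("ordered", "paired", "ranked")
MODES = ("constant_fixed", "constant_random", "adaptive")
INTERFACES = ("buttons", "keypad", "matrix", "text", "recording")
FEEDBACK = ("overall", "item_specific", "none")


@dataclass(frozen=True)
class PhaseSpec:
    name: str
    condition: str | None = None
    n_trials: int | None = None
    practice: bool = False


@dataclass(frozen=True)
class TaskSpec:
    """Declarative description of one listening task."""

    structure: str = "ordered"
    mode: str = "constant_fixed"
    response_interface: str = "buttons"
    button_labels: tuple[str, ...] = ()
    matrix_keyword_slots: int = 0
    feedback: str = "none"
    allow_repeat: bool = False
    max_trials: int | None = None
    n_runs: int = 1
    phases: tuple[PhaseSpec, ...] = ()
    phase_order: str = "fixed"
    practice_phase: PhaseSpec | None = None
    instructions_pre: str = ""
    instructions_post: str = ""

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}, got {self.structure!r}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.response_interface not in INTERFACES:
            raise ValueError(f"response_interface must be one of {INTERFACES}")
        if self.feedback not in FEEDBACK:
            raise ValueError(f"feedback must be one of {FEEDBACK}")
        if self.response_interface == "buttons" and len(self.button_labels) > 5:
            raise ValueError(f"at most 5 button labels, got {len(self.button_labels)}")
        if self.response_interface == "matrix" and self.matrix_keyword_slots > 5:
            raise ValueError(f"matrix supports at most 5 keyword slots, got {self.matrix_keyword_slots}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be ≥ 1")
        if self.phase_order not in ("fixed", "randomized"):
            raise ValueError("phase_order must be 'fixed' or 'randomized'")
        object.__setattr__(self, "button_labels", tuple(self.button_labels))
        object.__setattr__(self, "phases", tuple(self.phases))

    def to_dict(self) -> dict:
        d = {
            "structure": self.structure,
            "mode": self.mode,
            "response_interface": self.response_interface,
            "button_labels": list(self.button_labels),
            "matrix_keyword_slots": self.matrix_keyword_slots,
            "feedback": self.feedback,
            "allow_repeat": self.allow_repeat,
            "max_trials": self.max_trials,
            "n_runs": self.n_runs,
            "phases": [vars(p) for p in self.phases],
            "phase_order": self.phase_order,
            "practice_phase": vars(self.practice_phase) if self.practice_phase else None,
            "instructions_pre": self.instructions_pre,
            "instructions_post": self.instructions_post,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        d = dict(d)
        d["phases"] = tuple(PhaseSpec(**p) for p in d.get("phases", []))
        if d.get("practice_phase"):
            d["practice_phase"] = PhaseSpec(**d["practice_phase"])
        d["button_labels"] = tuple(d.get("button_labels", ()))
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TaskSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Ordered structure

def ordered_next_stimulus(
    task: TaskSpec,
    manifest: StimulusManifest,
    history,
    *,
    seed: int = 0,
    level: float | None = None,
    rng: np.random.Generator | None = None,
) -> ManifestRow:
    """Select the next stimulus of an ordered task.

    ``constant_fixed`` steps through the manifest in order;
    ``constant_random`` follows a seeded permutation without replacement
    (the same seed replays the same order); ``adaptive`` returns a
    manifest row whose difficulty level equals ``level`` (the staircase's
    current level), drawn at random among matches when ``rng`` is given.
    """
    n_done = len(history)
    if task.mode == "constant_fixed":
        if n_done >= len(manifest):
            raise IndexError("ordered task complete: all stimuli presented")
        return manifest.rows[n_done]
    if task.mode == "constant_random":
        if n_done >= len(manifest):
            raise IndexError("ordered task complete: all stimuli presented")
        perm = np.random.default_rng(seed).permutation(len(manifest))
        return manifest.rows[perm[n_done]]
    # adaptive
    if level is None:
        raise ValueError("adaptive mode needs the staircase's current level")
    matches = manifest.by_level(level)
    if not matches:
        raise LookupError(
            f"no manifest row at difficulty level {level}; available levels: {manifest.levels}"
        )
    if rng is not None and len(matches) > 1:
        return matches[int(rng.integers(len(matches)))]
    return matches[0]


# ---------------------------------------------------------------------------
# Paired structure

def paired_comparisons(
    set_a,
    set_b=None,
    *,
    order_balance: bool = False,
    rng: np.random.Generator | None = None,
    within_set: bool = False,
) -> list[tuple]:
    """Enumerate paired comparisons.

    Default: the cross product A×B (every stimulus of one set against
    every stimulus of the other — comparing two processing conditions
    item by item). With ``within_set`` instead all C(n,2) unordered pairs
    of ``set_a``. ``order_balance`` randomizes within-pair presentation
    order per pair using ``rng`` (seeded → reproducible).
    """
    set_a = list(set_a)
    if within_set:
        if len(set_a) < 2:
            raise ValueError("within-set pairing needs at least 2 stimuli")
        pairs = [(set_a[i], set_a[j]) for i in range(len(set_a)) for j in range(i + 1, len(set_a))]
    else:
        set_b = list(set_b) if set_b is not None else []
        if not set_a or not set_b:
            raise ValueError("paired comparison needs two nonempty stimulus sets")
        pairs = [(a, b) for a in set_a for b in set_b]
    if order_balance:
        if rng is None:
            rng = np.random.default_rng(0)
        pairs = [(b, a) if rng.integers(2) else (a, b) for a, b in pairs]
    return pairs


# ---------------------------------------------------------------------------
# Ranked structure: binary insertion by midpoint comparisons

@dataclass(frozen=True)
class RankingState:
    """Progress of a binary-insertion ranking.

    ``ranked`` is best→worst so far. ``active`` is
    (candidate, low, high): the candidate may still be inserted at any
    position in [low, high] of the ranked list; each comparison against
    the midpoint element halves that interval.
    """

    ranked: tuple = ()
    pending: tuple = ()
    active: tuple | None = None  # (candidate_id, low, high)
    comparisons_made: int = 0

    @property
    def done(self) -> bool:
        return self.active is None and not self.pending


def new_ranking(stimulus_ids) -> RankingState:
    ids = tuple(stimulus_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("stimulus ids must be unique")
    if not ids:
        raise ValueError("ranking needs at least one stimulus")
    return RankingState(ranked=ids[:1], pending=ids[1:])


def _activate_next(state: RankingState) -> RankingState:
    if state.active is not None or not state.pending:
        return state
    candidate, rest = state.pending[0], state.pending[1:]
    return replace(state, pending=rest, active=(candidate, 0, len(state.ranked)))


def ranking_next_comparison(state: RankingState) -> tuple | None:
    """Next (candidate, probe) pair to present, or None when the ranking
    is complete. The probe is the midpoint element of the candidate's
    remaining insertion interval (even intervals round toward the
    better-ranked end)."""
    state = _activate_next(state)
    if state.active is None:
        return None
    candidate, low, high = state.active
    mid = (low + high) // 2
    return candidate, state.ranked[mid]


def ranking_record_outcome(state: RankingState, winner) -> RankingState:
    """Record a judgment for the active comparison and halve the interval.

    ``winner`` must be the candidate or the probe. When the interval
    collapses, the candidate is inserted and the next pending stimulus is
    activated. Any sequence of judgments — consistent or not — yields a
    total order; with a transitive comparator it is the true order.
    """
    state = _activate_next(state)
    if state.active is None:
        raise RuntimeError("ranking already complete; no active comparison")
    candidate, low, high = state.active
    mid = (low + high) // 2
    probe = state.ranked[mid]
    if winner == candidate:
        high = mid  # candidate outranks the probe
    elif winner == probe:
        low = mid + 1
    else:
        raise ValueError(f"winner {winner!r} is not in the active pair ({candidate!r}, {probe!r})")
    state = replace(state, comparisons_made=state.comparisons_made + 1)
    if low == high:
        ranked = state.ranked[:low] + (candidate,) + state.ranked[low:]
        return replace(state, ranked=ranked, active=None)
    return replace(state, active=(candidate, low, high))


def rank_with_comparator(stimulus_ids, prefer) -> tuple[RankingState, int]:
    """Drive a full ranking with a comparator ``prefer(a, b) -> winner``.

    Returns the finished state and the number of comparisons used.
    """
    state = new_ranking(stimulus_ids)
    while (pair := ranking_next_comparison(state)) is not None:
        state = ranking_record_outcome(state, prefer(*pair))
    return state, state.comparisons_made


# ---------------------------------------------------------------------------
# Session state machine

@dataclass(frozen=True)
class InactivityPolicy:
    """Two inactivity limits: warn first, terminate later."""

    warn_after_s: float = 60.0
    terminate_after_s: float = 180.0

    def __post_init__(self) -> None:
        if not self.warn_after_s < self.terminate_after_s:
            raise ValueError("warn_after_s must be smaller than terminate_after_s")


class Session:
    """Mutable session runner: trials, runs, and the inactivity clock.

    Statuses: ``running`` → ``warned`` (inactivity past the warning
    limit) → ``terminated`` (past the termination limit; partial results
    preserved), or ``complete`` when ``max_trials`` × ``n_runs`` trials
    are recorded. Responses reset the inactivity clock and clear a
    warning.
    """

    def __init__(self, task: TaskSpec, policy: InactivityPolicy):
        self.task = task
        self.policy = policy
        self.status = "running"
        self.idle_s = 0.0
        self.trials: list = []
        self.runs_completed = 0
        self._trials_this_run = 0

    def _check_open(self) -> None:
        if self.status in ("terminated", "complete"):
            raise RuntimeError(f"session is {self.status}; no further events accepted")

    def respond(self, record) -> str:
        """Record a trial response; resets the inactivity clock."""
        self._check_open()
        self.trials.append(record)
        self.idle_s = 0.0
        self.status = "running"
        self._trials_this_run += 1
        if self.task.max_trials is not None and self._trials_this_run >= self.task.max_trials:
            self.runs_completed += 1
            self._trials_this_run = 0
            if self.runs_completed >= self.task.n_runs:
                self.status = "complete"
        return self.status

    def tick(self, seconds: float) -> str:
        """Advance the inactivity clock without a response."""
        self._check_open()
        self.idle_s += seconds
        if self.idle_s > self.policy.terminate_after_s:
            self.status = "terminated"
        elif self.idle_s > self.policy.warn_after_s:
            self.status = "warned"
        return self.status


def advance_session(session: Session, event: tuple) -> str:
    """Event-tuple interface over :class:`Session`:
    ``("response", record)`` or ``("tick", seconds)``."""
    kind, payload = event
    if kind == "response":
        return session.respond(payload)
    if kind == "tick":
        return session.tick(float(payload))
    raise ValueError(f"unknown session event {kind!r}")
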