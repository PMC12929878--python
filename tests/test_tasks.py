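"""Task structures: ordered selection, paired comparisons, binary-insertion
ranking, and the session/inactivity state machine."""

import itertools
import math

import numpy as np
import pytest

from auditest import (
    InactivityPolicy,
    Session,
    TaskSpec,
    TrialRecord,
    advance_session,
    new_ranking,
    ordered_next_stimulus,
    paired_comparisons,
    ranking_next_comparison,
    ranking_record_outcome,
)
from auditest.session_io import ManifestRow, StimulusManifest
from auditest.tasks import PhaseSpec, rank_with_comparator


def _manifest(levels=None, n=3):
    if levels is None:
        rows = tuple(ManifestRow(filename=f"s{i}.wav") for i in range(n))
    else:
        rows = tuple(
            ManifestRow(filename=f"s{lv}.wav", difficulty_level=float(lv)) for lv in levels
        )
    return StimulusManifest(rows)


class TestOrdered:
    def test_constant_fixed_follows_manifest_order(self):
        task = TaskSpec(mode="constant_fixed")
        manifest = _manifest(n=3)
        picks = []
        for _ in range(3):
            picks.append(ordered_next_stimulus(task, manifest, picks).filename)
        assert picks == ["s0.wav", "s1.wav", "s2.wav"]

    def test_constant_random_is_seeded_permutation(self):
        task = TaskSpec(mode="constant_random")
        manifest = _manifest(n=8)
        def run(seed):
            picks = []
            for _ in range(8):
                picks.append(ordered_next_stimulus(task, manifest, picks, seed=seed).filename)
            return picks
        assert run(5) == run(5)  # replayable
        assert sorted(run(5)) == sorted(r.filename for r in manifest.rows)  # permutation
        assert run(5) != run(6)

    def test_adaptive_looks_up_difficulty_level(self):
        task = TaskSpec(mode="adaptive")
        manifest = _manifest(levels=range(-20, 21, 2))  # 21-row manifest
        row = ordered_next_stimulus(task, manifest, [], level=-2.0)
        assert row.difficulty_level == -2.0

    def test_adaptive_missing_level_errors(self):
        task = TaskSpec(mode="adaptive")
        manifest = _manifest(levels=[0, 2, 4])
        with pytest.raises(LookupError, match="difficulty level"):
            ordered_next_stimulus(task, manifest, [], level=-2.0)


class TestPaired:
    def test_cross_product_count(self):
        pairs = paired_comparisons(list("abc"), list("wxyz"))
        assert len(pairs) == 12
        assert set(pairs) == {(a, b) for a in "abc" for b in "wxyz"}

    def test_single_pair(self):
        assert paired_comparisons(["a"], ["b"]) == [("a", "b")]

    def test_order_balance_deterministic_under_seed(self):
        a = paired_comparisons(list("abc"), list("xyz"), order_balance=True,
                               rng=np.random.default_rng(3))
        b = paired_comparisons(list("abc"), list("xyz"), order_balance=True,
                               rng=np.random.default_rng(3))
        assert a == b
        assert {frozenset(p) for p in a} == {frozenset((x, y)) for x in "abc" for y in "xyz"}

    def test_within_set_mode(self):
        pairs = paired_comparisons(list("abcd"), within_set=True)
        assert len(pairs) == 6  # C(4,2)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            paired_comparisons([], ["a"])


class TestRanking:
    def test_single_stimulus_done_without_comparisons(self):
        state = new_ranking(["only"])
        assert ranking_next_comparison(state) is None
        assert state.ranked == ("only",)

    def test_third_insertion_needs_at_most_two_comparisons(self):
        # inserting into a ranked pair probes a midpoint element first and
        # needs at most ceil(log2 3) = 2 comparisons; 3 total for n = 3
        prefer = lambda x, y: min(x, y)  # latent order: a > b > c
        state = new_ranking(["a", "b"])
        pair = ranking_next_comparison(state)
        assert pair[1] in ("a",)  # probe is the midpoint of the 2-interval
        _, n = rank_with_comparator(["c", "a", "b"], prefer)
        assert n <= 1 + 2

    def test_exhaustive_all_permutations_n6(self):
        # a transitive comparator must reproduce the descending latent
        # order from every presentation order (720 cases)
        ids = list(range(6))
        prefer = lambda x, y: max(x, y)  # larger latent value wins
        for perm in itertools.permutations(ids):
            state, n = rank_with_comparator(perm, prefer)
            assert list(state.ranked) == sorted(ids, reverse=True)
            assert n <= sum(math.ceil(math.log2(k)) for k in range(2, 7))

    def test_comparison_bound_randomized_n50(self):
        rng = np.random.default_rng(99)
        bound = sum(math.ceil(math.log2(k)) for k in range(2, 51))
        for _ in range(10):
            ids = list(rng.permutation(50))
            state, n = rank_with_comparator(ids, lambda x, y: max(x, y))
            assert list(state.ranked) == sorted(ids, reverse=True)
            assert n <= bound

    def test_probe_always_prefers_probe_inserts_candidate_last(self):
        state, _ = rank_with_comparator(["a", "b", "c"], lambda cand, probe: probe)
        assert state.ranked[0] == "a"
        assert state.ranked[-1] == "c"

    def test_inconsistent_judgments_still_total_order(self):
        # fixed inconsistent transcript: winner alternates arbitrarily
        flips = iter([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        def fickle(cand, probe):
            return (cand, probe)[next(flips)]
        state, _ = rank_with_comparator(list("abcde"), fickle)
        assert sorted(state.ranked) == list("abcde")  # total order, no crash

    def test_winner_outside_pair_rejected(self):
        state = new_ranking(["a", "b"])
        with pytest.raises(ValueError, match="not in the active pair"):
            ranking_record_outcome(state, "zzz")


class TestSession:
    def _record(self, i=0):
        return TrialRecord(stimulus_id=f"s{i}.wav", response="x", response_time_ms=500.0)

    def test_warning_threshold(self):
        s = Session(TaskSpec(), InactivityPolicy(60, 180))
        assert s.tick(61) == "warned"

    def test_termination_preserves_trials(self):
        s = Session(TaskSpec(), InactivityPolicy(60, 180))
        s.respond(self._record(0))
        s.respond(self._record(1))
        assert s.tick(181) == "terminated"
        assert len(s.trials) == 2
        with pytest.raises(RuntimeError):
            s.respond(self._record(2))

    def test_response_resets_inactivity_clock(self):
        s = Session(TaskSpec(), InactivityPolicy(60, 180))
        s.tick(59)
        s.respond(self._record())
        assert s.tick(59) == "running"  # 59 s since the response: below limit
        assert s.tick(2) == "warned"    # now 61 s since the response

    def test_completion_after_max_trials_and_runs(self):
        task = TaskSpec(max_trials=2, n_runs=2)
        s = Session(task, InactivityPolicy(60, 180))
        statuses = [s.respond(self._record(i)) for i in range(4)]
        assert statuses == ["running", "running", "running", "complete"]
        assert s.runs_completed == 2

    def test_event_tuple_interface(self):
        s = Session(TaskSpec(), InactivityPolicy(60, 180))
        assert advance_session(s, ("response", self._record())) == "running"
        assert advance_session(s, ("tick", 61)) == "warned"
        with pytest.raises(ValueError):
            advance_session(s, ("dance", None))


class TestTaskSpecValidation:
    def test_limits_enforced(self):
        with pytest.raises(ValueError):
            TaskSpec(response_interface="buttons", button_labels=tuple("abcdef"))
        with pytest.raises(ValueError):
            TaskSpec(response_interface="matrix", matrix_keyword_slots=6)
        with pytest.raises(ValueError):
            TaskSpec(structure="circular")
        with pytest.raises(ValueError):
            TaskSpec(n_runs=0)

    def test_json_round_trip(self, tmp_path):
        task = TaskSpec(
            structure="ordered", mode="adaptive", response_interface="keypad",
            n_runs=2, phases=(PhaseSpec(name="main", condition="NOISY"),),
            practice_phase=PhaseSpec(name="practice", practice=True),
        )
        path = tmp_path / "task.json"
        task.to_json(path)
        assert TaskSpec.from_json(path) == task
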