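import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from taskfmri_qc import behavior_qc
from taskfmri_qc.errors import ValidationError

from conftest import make_events


def longest_run_oracle(missing):
    """O(n^2): check every substring for being all-missing."""
    n = len(missing)
    best = 0
    for i in range(n):
        for j in range(i, n):
            if all(missing[i:j + 1]):
                best = max(best, j - i + 1)
    return best


def _events_from_missing(missing, run_id="sub-001"):
    responses = [None if m else ("LEFT" if i % 2 else "RIGHT")
                 for i, m in enumerate(missing)]
    return make_events([float(i) * 8 for i in range(len(missing))],
                       responses=responses, run_id=run_id)


class TestTrialCounts:
    def test_matching_counts_pass(self):
        ev = make_events([float(i) for i in range(64)],
                         trial_types=["CONTROL", "TASK"] * 32)
        mismatch, counts, msgs = behavior_qc.check_trial_counts(
            ev, {"CONTROL": 32, "TASK": 32})
        assert not mismatch and counts == {"CONTROL": 32, "TASK": 32} and not msgs

    def test_short_count_named(self):
        ev = make_events([float(i) for i in range(63)],
                         trial_types=["CONTROL"] * 31 + ["TASK"] * 32)
        mismatch, _, msgs = behavior_qc.check_trial_counts(
            ev, {"CONTROL": 32, "TASK": 32})
        assert mismatch and any("CONTROL" in m for m in msgs)

    def test_unexpected_type_named(self):
        ev = make_events([0.0, 1.0, 2.0], trial_types=["CONTROL", "TASK", "ODDBALL"])
        mismatch, _, msgs = behavior_qc.check_trial_counts(
            ev, {"CONTROL": 1, "TASK": 1})
        assert mismatch and any("ODDBALL" in m for m in msgs)


class TestCriterionB:
    @pytest.mark.parametrize("usable,expected", [(64, False), (31, True), (32, False)])
    def test_half_boundary_is_strict(self, usable, expected):
        ev = _events_from_missing([False] * usable)
        exclude, frac = behavior_qc.evaluate_criterion_b(ev, expected_total=64)
        assert exclude is expected
        assert frac == usable / 64

    def test_external_usable_count_overrides_observed(self):
        ev = _events_from_missing([False] * 64)
        exclude, frac = behavior_qc.evaluate_criterion_b(ev, 64, usable_trials=20)
        assert exclude and frac == 20 / 64


class TestLongestNoResponseRun:
    def test_run_of_five(self):
        ev = _events_from_missing([False, True, True, True, True, True, False])
        assert behavior_qc.longest_no_response_run(ev) == 5

    def test_all_responded_is_zero(self):
        ev = _events_from_missing([False] * 10)
        assert behavior_qc.longest_no_response_run(ev) == 0

    def test_200_random_sequences_match_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            missing = list(rng.random(n) < 0.35)
            ev = _events_from_missing(missing)
            assert behavior_qc.longest_no_response_run(ev) == longest_run_oracle(missing)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            behavior_qc.longest_no_response_run(make_events([]))


class TestCriterionC:
    def test_fraction_component_at_26_of_64(self):
        # 26 scattered misses (never two in a row): 26/64 > 0.40
        missing = [bool((i % 2 == 0) and i < 52) for i in range(64)]
        ev = _events_from_missing(missing)
        exclude, run_comp, frac_comp, longest, frac = behavior_qc.evaluate_criterion_c(ev)
        assert sum(missing) == 26 and exclude and frac_comp and not run_comp
        assert frac == pytest.approx(26 / 64)

    def test_25_of_64_with_short_runs_keeps(self):
        missing = [bool((i % 2 == 0) and i < 50) for i in range(64)]
        ev = _events_from_missing(missing)
        exclude, *_ = behavior_qc.evaluate_criterion_c(ev)
        assert sum(missing) == 25 and not exclude

    def test_five_consecutive_alone_excludes(self):
        missing = [False] * 64
        missing[20:25] = [True] * 5
        ev = _events_from_missing(missing)
        exclude, run_comp, frac_comp, longest, frac = behavior_qc.evaluate_criterion_c(ev)
        assert exclude and run_comp and not frac_comp and longest == 5

    @given(st.lists(st.booleans(), min_size=1, max_size=60), st.integers(0, 2**31 - 1))
    def test_fraction_component_permutation_invariant(self, missing, seed):
        rng = np.random.default_rng(seed)
        ev = _events_from_missing(missing)
        shuffled = list(np.array(missing)[rng.permutation(len(missing))])
        ev2 = _events_from_missing(shuffled)
        _, _, frac1, _, f1 = behavior_qc.evaluate_criterion_c(ev)
        _, _, frac2, _, f2 = behavior_qc.evaluate_criterion_c(ev2)
        assert frac1 == frac2 and f1 == pytest.approx(f2)


class TestResponseSummary:
    def test_mixed_trials(self):
        ev = make_events([0.0, 8.0, 16.0], responses=["LEFT", "RIGHT", None],
                         corrects=[True, False, None])
        by_key, total, acc = behavior_qc.response_summary(ev)
        assert by_key == {"LEFT": 1, "RIGHT": 1} and total == 2 and acc == 0.5

    def test_perfect_run(self):
        ev = make_events([float(i) * 8 for i in range(64)],
                         responses=["LEFT", "RIGHT"] * 32, corrects=[True] * 64)
        _, total, acc = behavior_qc.response_summary(ev)
        assert total == 64 and acc == 1.0

    def test_random_table_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        n = 80
        responses = [rng.choice(["LEFT", "RIGHT", None]) for _ in range(n)]
        corrects = [None if r is None else bool(rng.random() < 0.8) for r in responses]
        ev = make_events([float(i) * 5 for i in range(n)], responses=responses,
                         corrects=corrects)
        by_key, total, acc = behavior_qc.response_summary(ev)
        exp_total = sum(1 for r in responses if r is not None)
        assert total == exp_total
        assert by_key.get("LEFT", 0) == sum(1 for r in responses if r == "LEFT")
        assert by_key.get("RIGHT", 0) == sum(1 for r in responses if r == "RIGHT")
        n_correct = sum(1 for c in corrects if c is True)
        assert acc == pytest.approx(n_correct / exp_total)

    def test_no_correctness_column_suppresses_accuracy(self):
        ev = make_events([0.0, 8.0], responses=["LEFT", "RIGHT"],
                         corrects=[None, None])
        _, _, acc = behavior_qc.response_summary(ev)
        assert acc is None


class TestSingleButton:
    def test_forty_left_only_flags(self):
        ev = make_events([float(i) * 8 for i in range(40)], responses=["LEFT"] * 40)
        assert behavior_qc.detect_single_button(ev)

    def test_one_other_key_unflags(self):
        ev = make_events([float(i) * 8 for i in range(40)],
                         responses=["LEFT"] * 39 + ["RIGHT"])
        assert not behavior_qc.detect_single_button(ev)

    def test_too_few_responses_is_insufficient_evidence(self):
        ev = make_events([float(i) * 8 for i in range(5)], responses=["LEFT"] * 5)
        assert not behavior_qc.detect_single_button(ev, min_responses=10)


class TestSummarizeBehavior:
    def test_response_fraction_identity(self):
        missing = [bool(i % 3 == 0) for i in range(30)]
        ev = _events_from_missing(missing)
        res = behavior_qc.summarize_behavior(ev)
        assert res.n_responses_total + res.n_no_response == res.n_trials
        assert res.frac_no_response + res.n_responses_total / res.n_trials == \
               pytest.approx(1.0)

    def test_messages_distinguish_components(self):
        missing = [False] * 64
        missing[10:16] = [True] * 6
        res = behavior_qc.summarize_behavior(_events_from_missing(missing))
        assert res.flags.criterion_c_exclude
        assert any("in a row" in m for m in res.messages)
        assert not any("more than" in m for m in res.messages)
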