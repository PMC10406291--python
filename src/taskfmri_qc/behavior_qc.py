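"""Task-presentation (criterion B) and task-performance (criterion C) checks.

Criterion B excludes a run when fewer than half of the expected trials have
usable data (strict: exactly half keeps).  Criterion C excludes when the
participant failed to respond to five or more trials in a row (inclusive)
or to more than 40% of all trials (strict) — thresholds adopted from HCP
task protocols.  Single-button responding is surfaced as a review flag,
never an automatic exclusion.
"""
from __future__ import annotations

from collections import Counter
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .types import BehaviorFlags, BehaviorResult, EventsTable

DEFAULT_MAX_NO_RESPONSE_RUN = 5
DEFAULT_MAX_NO_RESPONSE_FRAC = 0.40
DEFAULT_MIN_RESPONSES_SINGLE_BUTTON = 10


def check_trial_counts(events: EventsTable,
                       expected_by_type: Mapping[str, int]) -> tuple[bool, dict[str, int], list[str]]:
    """Compare per-type trial counts against the expected design.

    Returns (counts_mismatch, observed counts, human-readable mismatch
    messages).  A mismatch is a QC finding, not an exception.
    """
    if not expected_by_type:
        raise ValidationError("expected_by_type must be non-empty")
    observed = dict(Counter(t for t in events.trials["trial_type"] if t is not None))
    messages: list[str] = []
    for ttype, expected in expected_by_type.items():
        got = observed.get(ttype, 0)
        if got != expected:
            messages.append(
                f"run {events.run_id}: {ttype} has {got} trials, expected {expected}"
            )
    for ttype in observed:
        if ttype not in expected_by_type:
            messages.append(
                f"run {events.run_id}: unexpected trial type {ttype!r} "
                f"({observed[ttype]} trials)"
            )
    return bool(messages), observed, messages


def evaluate_criterion_b(events: EventsTable, expected_total: int,
                         usable_trials: int | None = None) -> tuple[bool, float]:
    """Exclude when usable trials are fewer than half of those expected.

    ``usable_trials`` defaults to the observed trial count (run-truncation
    model); pass an externally derived count (e.g. after discounting
    censor-affected trials) to tighten the rule.
    """
    if expected_total <= 0:
        raise ValidationError("expected_total must be > 0")
    if usable_trials is None:
        usable_trials = events.n_trials
    if not 0 <= usable_trials <= expected_total:
        raise ValidationError("usable_trials must be in [0, expected_total]")
    fraction = usable_trials / expected_total
    return fraction < 0.5, fraction


def longest_no_response_run(events: EventsTable) -> int:
    """Length of the longest consecutive block of no-response trials."""
    if events.n_trials == 0:
        raise ValidationError("events table is empty")
    missing = ~events.responded
    longest = current = 0
    for m in missing:
        current = current + 1 if m else 0
        longest = max(longest, current)
    return longest


def evaluate_criterion_c(events: EventsTable,
                         max_run: int = DEFAULT_MAX_NO_RESPONSE_RUN,
                         max_frac: float = DEFAULT_MAX_NO_RESPONSE_FRAC,
                         ) -> tuple[bool, bool, bool, int, float]:
    """Invalid-performance decision from no-response trials.

    Returns (exclude, run_component, frac_component, longest_run,
    frac_no_response).  The two components are reported separately so the
    report can say which rule fired.
    """
    if events.n_trials == 0:
        raise ValidationError("events table is empty")
    longest = longest_no_response_run(events)
    n_missing = int((~events.responded).sum())
    frac = n_missing / events.n_trials
    run_component = longest >= max_run
    frac_component = frac > max_frac
    return run_component or frac_component, run_component, frac_component, longest, frac


def response_summary(events: EventsTable) -> tuple[dict[str, int], int, float | None]:
    """Per-key response counts, total, and accuracy among responded trials.

    No-response trials are neither correct nor incorrect, so the accuracy
    denominator is the responded-trial count.  Accuracy is None when no
    correctness information exists (column absent) or nothing was responded.
    """
    responded = events.trials[events.responded]
    by_key = dict(Counter(responded["response"]))
    total = len(responded)
    correct_vals = [v for v in responded["correct"] if v is not None]
    accuracy = sum(bool(v) for v in correct_vals) / total if correct_vals and total else None
    return by_key, total, accuracy


def detect_single_button(events: EventsTable,
                         min_responses: int = DEFAULT_MIN_RESPONSES_SINGLE_BUTTON) -> bool:
    """Flag a run where every response used the same key.

    Requires at least ``min_responses`` responses to count as evidence.
    This is a review flag for qualitative criterion C, not an exclusion.
    """
    by_key, total, _ = response_summary(events)
    nonzero = [k for k, v in by_key.items() if v > 0]
    return total >= min_responses and len(nonzero) == 1


def summarize_behavior(events: EventsTable,
                       expected_by_type: Mapping[str, int] | None = None,
                       expected_total: int | None = None,
                       usable_trials: int | None = None,
                       max_run: int = DEFAULT_MAX_NO_RESPONSE_RUN,
                       max_frac: float = DEFAULT_MAX_NO_RESPONSE_FRAC,
                       min_responses_single_button: int = DEFAULT_MIN_RESPONSES_SINGLE_BUTTON,
                       ) -> BehaviorResult:
    """Run every behavioral check and assemble a :class:`BehaviorResult`.

    ``expected_total`` defaults to the sum of ``expected_by_type`` when
    given, else to the observed trial count (criterion B then trivially
    passes, reflecting that the expected design is user configuration).
    """
    messages: list[str] = []
    if expected_by_type is not None:
        mismatch, observed, msgs = check_trial_counts(events, expected_by_type)
        messages.extend(msgs)
        expected_map: dict[str, int] | None = dict(expected_by_type)
    else:
        mismatch = False
        observed = dict(Counter(t for t in events.trials["trial_type"] if t is not None))
        expected_map = None

    if expected_total is None:
        expected_total = (sum(expected_by_type.values()) if expected_by_type
                          else events.n_trials)
    b_exclude, usable_fraction = evaluate_criterion_b(events, expected_total, usable_trials)
    if b_exclude:
        messages.append(
            f"run {events.run_id}: only {usable_fraction:.0%} of expected trials usable "
            f"(criterion B)"
        )

    c_exclude, run_comp, frac_comp, longest, frac = evaluate_criterion_c(
        events, max_run=max_run, max_frac=max_frac
    )
    if run_comp:
        messages.append(
            f"run {events.run_id}: {max_run} or more no-response trials in a row "
            f"(longest run {longest})"
        )
    if frac_comp:
        messages.append(
            f"run {events.run_id}: more than {max_frac:.0%} no-response trials "
            f"({frac:.1%})"
        )

    by_key, total, accuracy = response_summary(events)
    single = detect_single_button(events, min_responses_single_button)
    if single:
        messages.append(f"run {events.run_id}: only one response button used (review)")

    n_missing = events.n_trials - total
    return BehaviorResult(
        run_id=events.run_id,
        counts_by_type=observed,
        expected_by_type=expected_map,
        n_trials=events.n_trials,
        usable_fraction=usable_fraction,
        n_responses_by_key=by_key,
        n_responses_total=total,
        n_no_response=n_missing,
        frac_no_response=n_missing / events.n_trials,
        longest_no_response_run=longest,
        accuracy_responded=accuracy,
        flags=BehaviorFlags(
            criterion_b_exclude=b_exclude,
            criterion_c_exclude=c_exclude,
            single_button=single,
            counts_mismatch=mismatch,
        ),
        messages=messages,
    )
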