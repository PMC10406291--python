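"""Framewise displacement, frame censoring, and the excessive-motion rule.

FD follows the Power-style backward-difference sum: the absolute frame-to-
frame change in each translation axis, plus each rotation change converted
to arc length on a 50 mm sphere.  Frames with FD above a threshold
(default 0.9 mm, strict) are censored; a run is excluded (criterion A) when
the censored fraction reaches 0.20 (inclusive).
"""
from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .types import CensorResult, EventsTable, MotionRecord, TrialCensorOverlap

DEFAULT_FD_THRESHOLD_MM = 0.9
DEFAULT_EXCLUDE_FRACTION = 0.20
DEFAULT_HEAD_RADIUS_MM = 50.0


def compute_fd(motion: MotionRecord, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Per-frame framewise displacement in mm.

    fd[0] = 0; fd[t] = sum_i |d trans_i| + r * sum_i |d rot_i| with backward
    differences over the three axes.  Rotations are radians, so r converts
    them to mm of arc on a sphere of radius ``head_radius_mm``.
    """
    if not np.isfinite(motion.trans).all() or not np.isfinite(motion.rot).all():
        raise ValidationError("motion parameters must be finite")
    if not np.isfinite(head_radius_mm):
        raise ValidationError("head_radius_mm must be finite")
    fd = np.zeros(motion.n_frames)
    if motion.n_frames > 1:
        dt = np.abs(np.diff(motion.trans, axis=0)).sum(axis=1)
        dr = np.abs(np.diff(motion.rot, axis=0)).sum(axis=1)
        fd[1:] = dt + head_radius_mm * dr
    return fd


def censor_frames(fd: np.ndarray, threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
                  frac_threshold: float = DEFAULT_EXCLUDE_FRACTION,
                  censor_before: int = 0, censor_after: int = 0,
                  run_id: str = "run") -> CensorResult:
    """Censor frames with FD strictly above ``threshold_mm``.

    ``censor_before``/``censor_after`` optionally extend censoring to
    adjacent frames (0 by default: single-frame censoring).  The returned
    result already carries the criterion-A decision at ``frac_threshold``.
    """
    fd = np.asarray(fd, dtype=float)
    if threshold_mm < 0:
        raise ValidationError("threshold_mm must be >= 0")
    if np.any(fd < 0):
        raise ValidationError("fd values must be >= 0")
    mask = fd > threshold_mm
    if censor_before or censor_after:
        if censor_before < 0 or censor_after < 0:
            raise ValidationError("censor extensions must be >= 0")
        extended = mask.copy()
        for idx in np.flatnonzero(mask):
            lo = max(0, idx - censor_before)
            hi = min(fd.size, idx + censor_after + 1)
            extended[lo:hi] = True
        mask = extended
    n_censored = int(mask.sum())
    frac = n_censored / fd.size if fd.size else 0.0
    result = CensorResult(
        run_id=run_id,
        threshold_mm=float(threshold_mm),
        censor_mask=mask,
        n_censored=n_censored,
        frac_censored=frac,
        exclude_run=False,
        frac_threshold=float(frac_threshold),
    )
    result.exclude_run = evaluate_criterion_a(result, frac_threshold)
    return result


def evaluate_criterion_a(censor: CensorResult,
                         frac_threshold: float = DEFAULT_EXCLUDE_FRACTION) -> bool:
    """Exclude the run when the censored fraction reaches the threshold.

    The comparison is inclusive (>=): a run with exactly 20% of frames
    censored is excluded.
    """
    return bool(censor.frac_censored >= frac_threshold)


def trial_censor_overlap(events: EventsTable, censor: CensorResult,
                         frame_times: np.ndarray) -> TrialCensorOverlap:
    """Partition censored frames by whether they fall inside trial windows.

    A trial is affected when any censored frame's acquisition time lies in
    [onset, onset + duration).  Not all censored frames matter equally:
    motion outside trials costs fewer analyzable trials than motion during
    them, so the split is reported alongside criterion A.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.shape != censor.censor_mask.shape:
        raise ValidationError("frame_times length must equal the censor mask length")
    if frame_times.size > 1 and np.any(np.diff(frame_times) <= 0):
        raise ValidationError("frame_times must be strictly increasing")

    onsets = events.trials["onset"].to_numpy(dtype=float)
    durations = np.nan_to_num(events.trials["duration"].to_numpy(dtype=float), nan=0.0)
    censored_times = frame_times[censor.censor_mask]

    affected = np.zeros(events.n_trials, dtype=bool)
    in_any_trial = np.zeros(censored_times.size, dtype=bool)
    for i, (onset, dur) in enumerate(zip(onsets, durations)):
        inside = (censored_times >= onset) & (censored_times < onset + dur)
        affected[i] = bool(inside.any())
        in_any_trial |= inside
    n_in = int(in_any_trial.sum())
    return TrialCensorOverlap(
        affected=affected,
        n_trials_affected=int(affected.sum()),
        n_censored_in_trials=n_in,
        n_censored_outside_trials=int(censor.n_censored - n_in),
    )
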