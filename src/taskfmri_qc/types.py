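"""Core data model for per-run QC artifacts.

Missing values follow the BIDS convention: they are read from "n/a" cells
and held as NaN (numeric columns) or ``None`` (label columns).  A trial with
no recorded response key also has no response time; this is normalized at
construction so downstream code can test either column.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import ValidationError

EVENT_COLUMNS = ["onset", "duration", "trial_type", "response", "response_time", "correct"]


def is_missing(value: Any) -> bool:
    """True for BIDS-missing cells (None / NaN / pd.NA)."""
    return value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA


@dataclass
class EventsTable:
    """Per-trial task presentation and response record for one run.

    ``trials`` holds one row per trial with columns onset, duration,
    trial_type, response, response_time, correct.  Rows are sorted by onset;
    onsets are finite and non-negative; response times, when present, are
    positive seconds.
    """

    run_id: str
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.trials.copy()
        for col in EVENT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("onset", "duration", "response_time") else None
        df = df[EVENT_COLUMNS]
        onsets = pd.to_numeric(df["onset"], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(onsets)) or np.any(onsets < 0):
            raise ValidationError(f"run {self.run_id}: onsets must be finite and >= 0")
        df = df.sort_values("onset", kind="stable").reset_index(drop=True)
        # hold label columns as object so missing is always None, never NaN
        # coerced through a bool/str dtype
        df["response"] = np.array(
            [None if pd.isna(v) else str(v) for v in df["response"]], dtype=object
        )
        df["correct"] = np.array(
            [None if pd.isna(v) else bool(v) for v in df["correct"]], dtype=object
        )
        # normalize: a trial without a response key has no response time either
        no_resp = df["response"].isna()
        df.loc[no_resp, "response_time"] = np.nan
        df["correct"] = df["correct"].where(~no_resp, None)
        rt = pd.to_numeric(df["response_time"], errors="coerce")
        if (rt <= 0).any():
            raise ValidationError(f"run {self.run_id}: response_time must be > 0 when present")
        self.trials = df

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def responded(self) -> np.ndarray:
        """Boolean per-trial mask: a response key was recorded."""
        return (~self.trials["response"].isna()).to_numpy()


@dataclass
class MotionRecord:
    """Six realignment parameters plus framewise displacement for one run.

    Translations are millimetres, rotations radians (fMRIPrep convention).
    ``fd`` is millimetres; fd[0] is 0 because the first frame has no
    predecessor.  ``fd_source`` records whether FD came from the confounds
    file or was computed here.
    """

    run_id: str
    trans: np.ndarray  # (n_frames, 3) mm
    rot: np.ndarray  # (n_frames, 3) rad
    fd: np.ndarray | None = None  # (n_frames,) mm
    fd_source: str = "computed"  # {"file", "computed"}

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=float)
        self.rot = np.asarray(self.rot, dtype=float)
        if self.trans.ndim != 2 or self.trans.shape[1] != 3:
            raise ValidationError("trans must be (n_frames, 3)")
        if self.rot.shape != self.trans.shape:
            raise ValidationError("rot must match trans shape")
        if self.trans.shape[0] < 1:
            raise ValidationError("need at least one frame")
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if self.fd.shape != (self.n_frames,):
                raise ValidationError("fd length must equal n_frames")
            if np.any(self.fd < 0):
                raise ValidationError("fd values must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.trans.shape[0]


@dataclass
class RunImage:
    """A 4D preprocessed BOLD run plus its JSON sidecar metadata."""

    run_id: str
    data: np.ndarray  # (x, y, z, t)
    voxel_size: tuple[float, float, float]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError(f"run {self.run_id}: expected a 4D image, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValidationError(
                f"run {self.run_id}: need >= 2 timepoints for temporal summaries"
            )

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(self.data.shape)


@dataclass
class CensorResult:
    """Frame-censoring mask and the criterion-A (excessive motion) decision."""

    run_id: str
    threshold_mm: float
    censor_mask: np.ndarray  # (n_frames,) bool, True = censored
    n_censored: int
    frac_censored: float
    exclude_run: bool
    frac_threshold: float = 0.20

    @property
    def censored_frame_indices(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.censor_mask)]

    def to_record(self) -> dict[str, Any]:
        return {
            "threshold_mm": self.threshold_mm,
            "n_frames": int(self.censor_mask.size),
            "n_censored": int(self.n_censored),
            "frac_censored": float(self.frac_censored),
            "frac_threshold": self.frac_threshold,
            "exclude_run": bool(self.exclude_run),
            "censored_frame_indices": self.censored_frame_indices,
        }


@dataclass
class TrialCensorOverlap:
    """How censored frames line up with trial windows (criterion A x B)."""

    affected: np.ndarray  # per-trial bool
    n_trials_affected: int
    n_censored_in_trials: int
    n_censored_outside_trials: int


@dataclass
class BehaviorFlags:
    criterion_b_exclude: bool = False
    criterion_c_exclude: bool = False
    single_button: bool = False
    counts_mismatch: bool = False


@dataclass
class BehaviorResult:
    """Response counts and the criterion-B/C decisions for one run."""

    run_id: str
    counts_by_type: dict[str, int]
    expected_by_type: dict[str, int] | None
    n_trials: int
    usable_fraction: float
    n_responses_by_key: dict[str, int]
    n_responses_total: int
    n_no_response: int
    frac_no_response: float
    longest_no_response_run: int
    accuracy_responded: float | None
    flags: BehaviorFlags
    messages: list[str] = field(default_factory=list)

    def to_record(self) -> dict[str, Any]:
        return {
            "counts_by_type": self.counts_by_type,
            "expected_by_type": self.expected_by_type,
            "n_trials": self.n_trials,
            "usable_fraction": self.usable_fraction,
            "n_responses_by_key": self.n_responses_by_key,
            "n_responses_total": self.n_responses_total,
            "n_no_response": self.n_no_response,
            "frac_no_response": self.frac_no_response,
            "longest_no_response_run": self.longest_no_response_run,
            "accuracy_responded": self.accuracy_responded,
            "criterion_b_exclude": self.flags.criterion_b_exclude,
            "criterion_c_exclude": self.flags.criterion_c_exclude,
            "single_button": self.flags.single_button,
            "counts_mismatch": self.flags.counts_mismatch,
            "messages": self.messages,
        }


@dataclass
class VolumeSummaries:
    """Voxelwise temporal mean, sd, and tSNR volumes for one run."""

    run_id: str
    mean_vol: np.ndarray
    sd_vol: np.ndarray
    tsnr_vol: np.ndarray
    n_frames_used: int
    zero_sd_voxel_count: int


@dataclass
class MetadataMismatch:
    """One acquisition field on which runs disagree (criterion-D evidence)."""

    field_name: str
    majority_value: Any  # None when no majority exists
    deviants: list[tuple[str, Any]]  # (run_id, value)

    @property
    def no_consensus(self) -> bool:
        return self.majority_value is None


CRITERION_D_STATES = ("pass", "needs_review", "fail_by_override")


@dataclass
class QCDecision:
    """Consolidated pass/fail record for one run across criteria A-D.

    Criterion D is qualitative: the tool never fails it on its own, only a
    recorded human override can, and that override must carry a note.
    """

    run_id: str
    criterion_a: str  # pass | fail
    criterion_b: str  # pass | fail
    criterion_c: str  # pass | fail
    criterion_d: str  # pass | needs_review | fail_by_override
    excluded: bool = False
    override_note: str | None = None

    def __post_init__(self) -> None:
        for name in ("criterion_a", "criterion_b", "criterion_c"):
            if getattr(self, name) not in ("pass", "fail"):
                raise ValidationError(f"{name} must be pass or fail")
        if self.criterion_d not in CRITERION_D_STATES:
            raise ValidationError(f"criterion_d must be one of {CRITERION_D_STATES}")
        if self.criterion_d == "fail_by_override" and not self.override_note:
            raise ValidationError("criterion D can only fail with a recorded override note")
        self.excluded = self.derive_excluded()

    def derive_excluded(self) -> bool:
        return (
            self.criterion_a == "fail"
            or self.criterion_b == "fail"
            or self.criterion_c == "fail"
            or self.criterion_d == "fail_by_override"
        )

    def to_record(self) -> dict[str, Any]:
        return {
            "run_id": self.run_id,
            "criterion_a": self.criterion_a,
            "criterion_b": self.criterion_b,
            "criterion_c": self.criterion_c,
            "criterion_d": self.criterion_d,
            "excluded": self.excluded,
            "override_note": self.override_note,
        }
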