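"""End-to-end orchestration: artifacts in, records and decisions out."""
from __future__ import annotations

import glob
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import behavior_qc, bids_io, image_qc, motion_qc, report
from .errors import ValidationError
from .types import EventsTable, MetadataMismatch, MotionRecord, QCDecision, RunImage


@dataclass
class QCConfig:
    """Thresholds and conventions for one QC pass (defaults per the criteria)."""

    fd_threshold_mm: float = motion_qc.DEFAULT_FD_THRESHOLD_MM
    censor_frac: float = motion_qc.DEFAULT_EXCLUDE_FRACTION
    head_radius_mm: float = motion_qc.DEFAULT_HEAD_RADIUS_MM
    censor_before: int = 0
    censor_after: int = 0
    max_no_resp_run: int = behavior_qc.DEFAULT_MAX_NO_RESPONSE_RUN
    max_no_resp_frac: float = behavior_qc.DEFAULT_MAX_NO_RESPONSE_FRAC
    expected_counts: dict[str, int] | None = None
    tr_s: float | None = None  # fallback when the sidecar lacks RepetitionTime


def frame_times_for(motion: MotionRecord, image: RunImage | None,
                    config: QCConfig) -> np.ndarray:
    """Frame acquisition times t*TR, with TR from the sidecar or config."""
    tr = None
    if image is not None:
        tr = image.metadata.get("RepetitionTime")
    if tr is None:
        tr = config.tr_s
    if tr is None:
        raise ValidationError(
            f"run {motion.run_id}: RepetitionTime absent from sidecar and no tr_s configured"
        )
    return np.arange(motion.n_frames) * float(tr)


def process_run(events: EventsTable | None, motion: MotionRecord | None,
                image: RunImage | None, config: QCConfig | None = None,
                run_id: str | None = None) -> report.RunRecord:
    """Run every applicable QC stage for one run's artifacts."""
    config = config or QCConfig()
    rid = run_id or next(
        a.run_id for a in (events, motion, image) if a is not None
    )
    rec = report.RunRecord(run_id=rid, events=events, motion=motion, image=image)

    if motion is not None:
        if motion.fd is None:
            motion.fd = motion_qc.compute_fd(motion, config.head_radius_mm)
            motion.fd_source = "computed"
        rec.censor = motion_qc.censor_frames(
            motion.fd, threshold_mm=config.fd_threshold_mm,
            frac_threshold=config.censor_frac,
            censor_before=config.censor_before, censor_after=config.censor_after,
            run_id=rid,
        )
        has_tr = config.tr_s is not None or (
            image is not None and image.metadata.get("RepetitionTime") is not None
        )
        if events is not None and has_tr:
            rec.overlap = motion_qc.trial_censor_overlap(
                events, rec.censor, frame_times_for(motion, image, config)
            )
    if events is not None:
        rec.behavior = behavior_qc.summarize_behavior(
            events, expected_by_type=config.expected_counts,
            max_run=config.max_no_resp_run, max_frac=config.max_no_resp_frac,
        )
    if image is not None:
        rec.summaries = image_qc.temporal_summaries(image)
    return rec


def process_dataset(artifacts: Sequence[tuple[EventsTable | None, MotionRecord | None,
                                              RunImage | None]],
                    config: QCConfig | None = None,
                    overrides: Mapping[str, tuple[str, str]] | None = None,
                    ) -> tuple[list[report.RunRecord], list[MetadataMismatch],
                               list[QCDecision]]:
    """QC every run, check cross-run metadata consistency, and decide."""
    config = config or QCConfig()
    records = [process_run(ev, mo, im, config) for ev, mo, im in artifacts]
    images = [r.image for r in records if r.image is not None]
    mismatches = (
        image_qc.detect_metadata_mismatch(images) if len(images) >= 3 else []
    )
    decisions = report.decide_all(records, mismatches, dict(overrides or {}))
    return records, mismatches, decisions


def discover_runs(bids_dir: str, confounds_dir: str | None = None
                  ) -> list[dict[str, str | None]]:
    """Find per-run artifact paths in a BIDS-like tree.

    Runs are keyed by the events-file stem; confounds may live beside the
    events (same func/ directory) or in a parallel derivatives tree.
    """
    entries = []
    for ev_path in sorted(glob.glob(os.path.join(bids_dir, "*", "func", "*_events.tsv"))):
        stem = ev_path[: -len("_events.tsv")]
        conf = stem + "_desc-confounds_timeseries.tsv"
        if not os.path.exists(conf) and confounds_dir:
            conf = os.path.join(confounds_dir, os.path.basename(conf))
        bold = next((p for p in (stem + "_bold.nii.gz", stem + "_bold.nii")
                     if os.path.exists(p)), None)
        sidecar = stem + "_bold.json"
        entries.append({
            "run_id": os.path.basename(stem).split("_")[0],
            "events": ev_path,
            "confounds": conf if os.path.exists(conf) else None,
            "bold": bold,
            "sidecar": sidecar if os.path.exists(sidecar) else None,
        })
    return entries


def load_runs(entries: Sequence[Mapping[str, str | None]], config: QCConfig | None = None
              ) -> list[tuple[EventsTable | None, MotionRecord | None, RunImage | None]]:
    config = config or QCConfig()
    out = []
    for e in entries:
        rid = e["run_id"]
        events = bids_io.read_events(e["events"], run_id=rid) if e.get("events") else None
        motion = (bids_io.read_confounds(e["confounds"], run_id=rid,
                                         head_radius_mm=config.head_radius_mm)
                  if e.get("confounds") else None)
        image = (bids_io.read_run_image(e["bold"], e.get("sidecar"), run_id=rid)
                 if e.get("bold") else None)
        out.append((events, motion, image))
    return out
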