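"""Synthetic task runs with known ground truth.

Generates the three per-run artifacts the QC pipeline consumes — events
tables, motion traces, and 4D ellipsoid "brain" phantoms — with planted
features (no-response blocks, motion spikes, tSNR targets, geometric
distortion) whose recovery exercises every QC stage without any download.

Defaults emulate the study conditions: 64 trials split evenly between
CONTROL and TASK at about 7 trials/min, LEFT/RIGHT response keys, response
times lognormal with median 0.8 s (sigma 0.3), FD spikes realized as
single-frame translation steps so the planted FD value is exact by
construction.  Identical seed and spec give identical outputs.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import bids_io
from .errors import ValidationError
from .motion_qc import compute_fd
from .types import EventsTable, MotionRecord, RunImage

RT_MEDIAN_S = 0.8
RT_SIGMA = 0.3


@dataclass
class MissingPattern:
    """Which trials lack a response: none, scattered(k), block(k, start), decaying(rate)."""

    kind: str = "none"
    k: int = 0
    start_index: int = 0
    rate: float = 0.0

    def indices(self, n_trials: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return np.array([], dtype=int)
        if self.kind == "scattered":
            if not 0 < self.k <= n_trials:
                raise ValidationError("scattered k must be in (0, n_trials]")
            # spread evenly so no long consecutive runs form
            return (np.arange(self.k) * n_trials // self.k).astype(int)
        if self.kind == "block":
            if not 0 < self.k <= n_trials or self.start_index + self.k > n_trials:
                raise ValidationError("block must fit inside the trial sequence")
            return np.arange(self.start_index, self.start_index + self.k)
        if self.kind == "decaying":
            # miss probability grows linearly over the run (waning attention)
            p = np.clip(self.rate * np.arange(n_trials) / max(n_trials - 1, 1), 0, 1)
            return np.flatnonzero(rng.random(n_trials) < p)
        raise ValidationError(f"unknown missing pattern kind {self.kind!r}")


@dataclass
class Spike:
    frame: int
    magnitude_mm: float


@dataclass
class Distortion:
    kind: str = "none"  # none | affine
    shear: float = 0.0
    scale: float = 1.0


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (24, 24, 12)
    brain_axes_vox: tuple[float, float, float] = (9.0, 11.0, 5.0)
    baseline: float = 1000.0
    tsnr_target: float = 50.0
    distortion: Distortion = field(default_factory=Distortion)


@dataclass
class SynthSpec:
    """Full recipe for one synthetic run."""

    seed: int = 0
    run_id: str = "sub-001"
    n_trials: int = 64
    trial_types: dict[str, float] = field(
        default_factory=lambda: {"CONTROL": 0.5, "TASK": 0.5}
    )
    trial_rate_per_min: float = 7.0
    trial_duration_s: float = 2.0
    response_keys: tuple[str, ...] = ("LEFT", "RIGHT")
    missing_pattern: MissingPattern = field(default_factory=MissingPattern)
    accuracy: float = 0.95
    n_frames: int = 280
    tr_s: float = 2.0
    spikes: list[Spike] = field(default_factory=list)
    drift_mm: float = 0.2
    phantom: PhantomSpec = field(default_factory=PhantomSpec)


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    # independent streams per artifact so changing one spec field does not
    # reshuffle the others
    return np.random.default_rng([spec.seed, stream])


def synth_events(spec: SynthSpec, out_path: str | None = None) -> EventsTable:
    """Generate one run's events table with the planted missing pattern."""
    rng = _rng(spec, 1)
    n = spec.n_trials
    iti = 60.0 / spec.trial_rate_per_min
    jitter = rng.uniform(-0.1 * iti, 0.1 * iti, n)
    onsets = 4.0 + np.arange(n) * iti + jitter  # small lead-in before trial 1

    labels: list[str] = []
    types = list(spec.trial_types.items())
    for ttype, prop in types[:-1]:
        labels += [ttype] * int(round(prop * n))
    labels += [types[-1][0]] * (n - len(labels))
    trial_type = rng.permutation(np.array(labels, dtype=object))

    missing_idx = spec.missing_pattern.indices(n, rng)
    responded = np.ones(n, dtype=bool)
    responded[missing_idx] = False

    response = np.array([None] * n, dtype=object)
    rt = np.full(n, np.nan)
    correct = np.array([None] * n, dtype=object)
    keys = rng.choice(list(spec.response_keys), n)
    rts = np.exp(rng.normal(np.log(RT_MEDIAN_S), RT_SIGMA, n))
    corrects = rng.random(n) < spec.accuracy
    response[responded] = keys[responded]
    rt[responded] = rts[responded]
    correct[responded] = [bool(c) for c in corrects[responded]]

    events = EventsTable(
        run_id=spec.run_id,
        trials=pd.DataFrame(
            {
                "onset": onsets,
                "duration": np.full(n, spec.trial_duration_s),
                "trial_type": trial_type,
                "response": response,
                "response_time": rt,
                "correct": correct,
            }
        ),
    )
    if out_path is not None:
        bids_io.write_events(events, out_path)
    return events


def synth_motion(spec: SynthSpec, out_path: str | None = None) -> MotionRecord:
    """Generate a motion trace: smooth drift plus exact planted FD spikes.

    Drift is a cumulative Gaussian walk scaled so each parameter's
    excursion stays within ``drift_mm`` (rotations within the arc-length
    equivalent).  Each spike is a persistent translation step at one frame,
    so its FD equals ``magnitude_mm`` exactly when drift is zero.
    """
    if spec.n_frames < 2:
        raise ValidationError("need n_frames >= 2")
    rng = _rng(spec, 2)
    n = spec.n_frames

    def walk(scale_mm: float) -> np.ndarray:
        w = np.cumsum(rng.normal(0, 1, n))
        peak = np.abs(w).max()
        return w * (scale_mm / peak) if peak > 0 and scale_mm > 0 else np.zeros(n)

    trans = np.column_stack([walk(spec.drift_mm) for _ in range(3)])
    rot = np.column_stack([walk(spec.drift_mm / 50.0) for _ in range(3)])

    sign = 1.0
    for spike in spec.spikes:
        if not 1 <= spike.frame < n:
            raise ValidationError(f"spike frame {spike.frame} outside [1, {n - 1}]")
        trans[spike.frame:, 0] += sign * spike.magnitude_mm
        sign = -sign  # alternate so the trace does not walk away

    record = MotionRecord(run_id=spec.run_id, trans=trans, rot=rot)
    record.fd = compute_fd(record)
    record.fd_source = "computed"
    if out_path is not None:
        bids_io.write_confounds(record, out_path)
    return record


def _ellipsoid_mask(phantom: PhantomSpec) -> np.ndarray:
    nx, ny, nz = phantom.shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    x, y, z = np.meshgrid(
        np.arange(nx) - cx, np.arange(ny) - cy, np.arange(nz) - cz, indexing="ij"
    )
    if phantom.distortion.kind == "affine":
        x, y = (
            phantom.distortion.scale * x + phantom.distortion.shear * y,
            y,
        )
    elif phantom.distortion.kind != "none":
        raise ValidationError(f"unknown distortion kind {phantom.distortion.kind!r}")
    ax, ay, az = phantom.brain_axes_vox
    return (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0


def synth_bold(spec: SynthSpec, image_path: str | None = None,
               sidecar_path: str | None = None) -> RunImage:
    """Generate a 4D ellipsoid phantom with a controlled in-brain tSNR.

    In-brain voxels get Gaussian temporal noise of sd baseline/tsnr_target
    around the baseline; background is exactly zero (so its temporal sd is
    zero).  A distorted phantom also gets a deviant sidecar — phase
    encoding along the other axis — to exercise metadata-mismatch
    detection, mimicking a run acquired with the wrong protocol.
    """
    ph = spec.phantom
    if ph.tsnr_target <= 0:
        raise ValidationError("tsnr_target must be > 0")
    if spec.n_frames < 2:
        raise ValidationError("need n_frames >= 2")
    rng = _rng(spec, 3)
    mask = _ellipsoid_mask(ph)
    t = spec.n_frames
    data = np.zeros(ph.shape + (t,))
    n_in = int(mask.sum())
    noise_sd = ph.baseline / ph.tsnr_target
    data[mask] = ph.baseline + rng.normal(0, noise_sd, (n_in, t))

    deviant = ph.distortion.kind != "none"
    metadata = {
        "RepetitionTime": spec.tr_s,
        "PhaseEncodingDirection": "i" if deviant else "j-",
        "TaskName": "synthetic",
    }
    image = RunImage(run_id=spec.run_id, data=data, voxel_size=(3.0, 3.0, 3.0),
                     metadata=metadata)
    if image_path is not None:
        bids_io.write_run_image(image, image_path, sidecar_path)
    return image


def brain_mask(spec: SynthSpec) -> np.ndarray:
    """The phantom's ground-truth brain mask (for recovery statistics)."""
    return _ellipsoid_mask(spec.phantom)


def synth_run(spec: SynthSpec, out_dir: str | None = None
              ) -> tuple[EventsTable, MotionRecord, RunImage]:
    """Generate all three artifacts for one run, optionally as a BIDS-like tree.

    Layout: ``out_dir/<run_id>/func/<run_id>_task-synth_{events.tsv,
    bold.nii.gz,bold.json,desc-confounds_timeseries.tsv}``.
    """
    paths = {}
    if out_dir is not None:
        func = os.path.join(out_dir, spec.run_id, "func")
        os.makedirs(func, exist_ok=True)
        stem = os.path.join(func, f"{spec.run_id}_task-synth")
        paths = {
            "events": f"{stem}_events.tsv",
            "confounds": f"{stem}_desc-confounds_timeseries.tsv",
            "bold": f"{stem}_bold.nii.gz",
            "sidecar": f"{stem}_bold.json",
        }
    events = synth_events(spec, paths.get("events"))
    motion = synth_motion(spec, paths.get("confounds"))
    image = synth_bold(spec, paths.get("bold"), paths.get("sidecar"))
    return events, motion, image


def example_cohort(seed: int = 0, n_clean: int = 4, n_frames: int = 200,
                   phantom: PhantomSpec | None = None) -> list[SynthSpec]:
    """A small cohort with one planted problem of each kind.

    ``n_clean`` unremarkable runs, plus: one run with a 5-trial no-response
    block (criterion C, consecutive rule), one with attention decaying
    until most late trials are missed (criterion C, fraction rule), one
    with enough motion spikes to censor a quarter of its frames
    (criterion A), and one acquired distorted with deviant sidecar
    metadata (criterion D evidence).
    """
    phantom = phantom or PhantomSpec()
    base = SynthSpec(seed=seed, n_frames=n_frames, phantom=phantom)
    specs = [
        replace(base, seed=seed + i, run_id=f"sub-{i + 1:03d}") for i in range(n_clean)
    ]
    nxt = n_clean + 1
    specs.append(replace(
        base, seed=seed + 101, run_id=f"sub-{nxt:03d}",
        missing_pattern=MissingPattern(kind="block", k=5, start_index=20),
    ))
    specs.append(replace(
        base, seed=seed + 102, run_id=f"sub-{nxt + 1:03d}",
        missing_pattern=MissingPattern(kind="decaying", rate=1.5),
    ))
    n_spikes = max(1, int(round(0.25 * n_frames)))
    step = max(1, n_frames // (n_spikes + 1))
    specs.append(replace(
        base, seed=seed + 103, run_id=f"sub-{nxt + 2:03d}",
        spikes=[Spike(frame=1 + i * step, magnitude_mm=1.5) for i in range(n_spikes)],
    ))
    specs.append(replace(
        base, seed=seed + 104, run_id=f"sub-{nxt + 3:03d}",
        phantom=replace(phantom, distortion=Distortion(kind="affine", shear=0.6, scale=1.3)),
    ))
    return specs
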