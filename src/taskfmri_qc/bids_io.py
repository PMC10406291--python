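"""Readers and writers for BIDS-style per-run artifacts.

Three inputs are handled: ``_events.tsv`` trial tables, fMRIPrep-style
``_desc-confounds_timeseries.tsv`` motion tables, and 4D NIfTI images with
JSON sidecars.  Missing cells are accepted as "n/a", "NA", or empty and
always written back as "n/a" (the BIDS convention).
"""
from __future__ import annotations

import json
import os
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .types import EventsTable, MotionRecord, RunImage

NA_VALUES = ["n/a", "NA", ""]
MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
DEFAULT_FD_COLUMN = "framewise_displacement"

_TRUTHY = {"1", "true", "yes", "y", "correct"}
_FALSY = {"0", "false", "no", "n", "incorrect"}


def _run_id_from_path(path: str) -> str:
    base = os.path.basename(path)
    for suffix in ("_events.tsv", "_desc-confounds_timeseries.tsv", ".tsv",
                   ".nii.gz", ".nii", "_bold"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return base or "run"


def _read_tsv(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False,
                       dtype=str)


def _numeric(series: pd.Series, column: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & ~series.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"column {column!r}, row {row + 2}: cannot parse {series.iloc[row]!r} as a number"
        )
    return out


def _coerce_correct(series: pd.Series) -> pd.Series:
    def one(v: Any) -> Any:
        if pd.isna(v):
            return None
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise ParseError(f"cannot parse correctness value {v!r}")

    return series.map(one)


def read_events(path: str, column_map: Mapping[str, str] | None = None,
                run_id: str | None = None) -> EventsTable:
    """Load a BIDS ``_events.tsv`` into an :class:`EventsTable`.

    ``column_map`` maps canonical names (e.g. ``response_time``) to the
    file's actual column names for dialects such as ``reaction_time``.
    Rows come back sorted by onset with "n/a" cells normalized to missing.
    """
    df = _read_tsv(path)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items() if v in df.columns}
    df = df.rename(columns=rename)
    if "response_time" not in df.columns and "reaction_time" in df.columns:
        df = df.rename(columns={"reaction_time": "response_time"})

    for required in ("onset", "trial_type"):
        if required not in df.columns:
            raise SchemaError(f"{path}: required column {required!r} is missing")

    out = pd.DataFrame()
    out["onset"] = _numeric(df["onset"], "onset")
    out["duration"] = _numeric(df["duration"], "duration") if "duration" in df.columns else np.nan
    out["trial_type"] = df["trial_type"].where(~df["trial_type"].isna(), None)
    out["response"] = df["response"].where(~df["response"].isna(), None) \
        if "response" in df.columns else None
    out["response_time"] = _numeric(df["response_time"], "response_time") \
        if "response_time" in df.columns else np.nan
    out["correct"] = _coerce_correct(df["correct"]) if "correct" in df.columns else None
    return EventsTable(run_id=run_id or _run_id_from_path(path), trials=out)


def write_events(events: EventsTable, path: str) -> None:
    """Write an EventsTable back to BIDS TSV, missing cells as "n/a"."""
    df = events.trials.copy()
    df["correct"] = np.array(
        [None if v is None else str(int(bool(v))) for v in df["correct"]], dtype=object
    )
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.4f")


def read_confounds(path: str, fd_column: str = DEFAULT_FD_COLUMN,
                   run_id: str | None = None, head_radius_mm: float = 50.0) -> MotionRecord:
    """Load an fMRIPrep confounds TSV into a :class:`MotionRecord`.

    The six realignment columns are required.  If the FD column is present
    its first-row "n/a" becomes 0 (no predecessor frame); if absent, FD is
    computed from the realignment parameters.
    """
    df = _read_tsv(path)
    for col in MOTION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: required motion column {col!r} is missing")
    trans = np.column_stack([_numeric(df[c], c) for c in MOTION_COLUMNS[:3]])
    rot = np.column_stack([_numeric(df[c], c) for c in MOTION_COLUMNS[3:]])
    rid = run_id or _run_id_from_path(path)

    if fd_column in df.columns:
        fd = _numeric(df[fd_column], fd_column).to_numpy(dtype=float)
        if np.isnan(fd[0]):
            fd[0] = 0.0
        if np.any(np.isnan(fd)):
            raise ValidationError(f"{path}: FD column has interior missing values")
        if np.any(fd < 0):
            raise ValidationError(f"{path}: FD values must be >= 0")
        return MotionRecord(run_id=rid, trans=trans, rot=rot, fd=fd, fd_source="file")

    from .motion_qc import compute_fd

    record = MotionRecord(run_id=rid, trans=trans, rot=rot)
    record.fd = compute_fd(record, head_radius_mm=head_radius_mm)
    record.fd_source = "computed"
    return record


def write_confounds(motion: MotionRecord, path: str, include_fd: bool = True) -> None:
    """Write a MotionRecord as an fMRIPrep-style confounds TSV."""
    df = pd.DataFrame(
        np.hstack([motion.trans, motion.rot]), columns=MOTION_COLUMNS
    )
    if include_fd and motion.fd is not None:
        col = motion.fd.astype(object).copy()
        col[0] = None  # fMRIPrep writes n/a for the first frame
        df[DEFAULT_FD_COLUMN] = col
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.6f")


def read_run_image(image_path: str, sidecar_path: str | None = None,
                   run_id: str | None = None) -> RunImage:
    """Load a 4D NIfTI (+optional JSON sidecar) into a :class:`RunImage`."""
    img = nib.load(image_path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError(f"{image_path}: expected a 4D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    metadata: dict[str, Any] = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            metadata = json.load(fh)
    return RunImage(
        run_id=run_id or _run_id_from_path(image_path),
        data=data.astype(np.float64),
        voxel_size=tuple(float(z) for z in zooms),
        metadata=metadata,
    )


def write_run_image(image: RunImage, image_path: str, sidecar_path: str | None = None) -> None:
    """Write a RunImage to NIfTI-1 plus an optional JSON sidecar."""
    affine = np.diag(list(image.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), image_path)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(image.metadata, fh, indent=1, sort_keys=True)
            fh.write("\n")
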