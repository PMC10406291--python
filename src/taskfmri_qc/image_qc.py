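"""Temporal summary images, review montages, and metadata-consistency checks.

Supports criterion D (failed acquisition/preprocessing), which is
qualitative: this module produces evidence — voxelwise temporal mean, sd,
and tSNR (mean/sd) volumes, slice montages for side-by-side review, and a
list of runs whose sidecar metadata or geometry deviates from the dataset
majority — but never an automatic exclusion.

Summaries use the entire run without censoring, which visually exaggerates
differences between runs (the point of a QC image).
"""
from __future__ import annotations

from collections import Counter
from typing import Any, Sequence

import numpy as np

from .errors import ValidationError
from .types import MetadataMismatch, RunImage, VolumeSummaries

DEFAULT_METADATA_FIELDS = ("PhaseEncodingDirection", "RepetitionTime")
MONTAGE_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


def temporal_summaries(image: RunImage, ddof: int = 1) -> VolumeSummaries:
    """Voxelwise temporal mean, sd, and tSNR over the full run.

    sd uses the sample (n-1) denominator by default (``ddof`` is exposed
    for cross-checking against toolchains that use n).  Voxels with zero
    temporal sd — e.g. background exactly at baseline — get tSNR 0 rather
    than infinity so montages render; their count is reported.
    """
    data = image.data
    if data.shape[3] < 2:
        raise ValidationError("need >= 2 timepoints")
    mean_vol = data.mean(axis=3)
    sd_vol = data.std(axis=3, ddof=ddof)
    zero_sd = sd_vol == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr_vol = np.where(zero_sd, 0.0, mean_vol / np.where(zero_sd, 1.0, sd_vol))
    return VolumeSummaries(
        run_id=image.run_id,
        mean_vol=mean_vol,
        sd_vol=sd_vol,
        tsnr_vol=tsnr_vol,
        n_frames_used=int(data.shape[3]),
        zero_sd_voxel_count=int(zero_sd.sum()),
    )


def montage_slice_indices(extent: int, n_slices: int, trim_frac: float = 0.10) -> np.ndarray:
    """Evenly spaced slice indices, skipping the outer ``trim_frac`` of the axis."""
    if n_slices < 1:
        raise ValidationError("n_slices must be >= 1")
    if n_slices > extent:
        raise ValidationError(f"n_slices {n_slices} exceeds axis extent {extent}")
    trim = int(round(trim_frac * extent))
    eligible = np.arange(trim, extent - trim)
    if n_slices > eligible.size:  # tiny axis: fall back to the full range
        eligible = np.arange(extent)
    if n_slices == 1:
        return eligible[[eligible.size // 2]]
    picks = np.round(np.linspace(0, eligible.size - 1, n_slices)).astype(int)
    return eligible[picks]


def montage(volume: np.ndarray, n_slices: int = 8, axis: str = "axial",
            n_cols: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Tile evenly spaced slices of a 3D volume into one 2D image.

    Slices are taken row-major along the named anatomical axis, excluding
    the outer 10% of the axis (mostly empty in a brain image).  Intensities
    are windowed to [0, 98th percentile of nonzero values] so a few bright
    vessels do not wash out the display.  Returns (tiled 2D array in [0,1],
    slice indices).
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValidationError("montage needs a 3D volume")
    if axis not in MONTAGE_AXES:
        raise ValidationError(f"axis must be one of {sorted(MONTAGE_AXES)}")
    ax = MONTAGE_AXES[axis]
    indices = montage_slice_indices(volume.shape[ax], n_slices)

    slices = [np.take(volume, i, axis=ax).T[::-1] for i in indices]
    nonzero = volume[volume != 0]
    vmax = float(np.percentile(nonzero, 98)) if nonzero.size else 1.0
    if vmax <= 0:
        vmax = 1.0
    slices = [np.clip(s / vmax, 0.0, 1.0) for s in slices]

    n_cols = n_cols or min(4, n_slices)
    n_rows = -(-n_slices // n_cols)
    h, w = slices[0].shape
    tiled = np.zeros((n_rows * h, n_cols * w))
    for k, s in enumerate(slices):
        r, c = divmod(k, n_cols)
        tiled[r * h:(r + 1) * h, c * w:(c + 1) * w] = s
    return tiled, indices


def _normalize_value(value: Any) -> Any:
    if isinstance(value, (list, tuple)):
        return tuple(_normalize_value(v) for v in value)
    if isinstance(value, float):
        return round(value, 6)
    return value


def detect_metadata_mismatch(runs: Sequence[RunImage],
                             fields: Sequence[str] = DEFAULT_METADATA_FIELDS,
                             check_geometry: bool = True) -> list[MetadataMismatch]:
    """Flag runs whose acquisition metadata deviates from the majority.

    For each sidecar field (plus spatial shape and voxel size when
    ``check_geometry``), the modal value across runs is taken as the
    dataset's intended acquisition; any run differing is listed.  A field
    with no unique mode is reported as a no-consensus mismatch.  Review
    evidence for criterion D, not an automatic exclusion.
    """
    if len(runs) < 3:
        raise ValidationError("need at least 3 runs to define a majority")

    checks: dict[str, list[tuple[str, Any]]] = {}
    for name in fields:
        checks[name] = [(r.run_id, _normalize_value(r.metadata.get(name))) for r in runs]
    if check_geometry:
        checks["spatial_shape"] = [(r.run_id, tuple(r.shape[:3])) for r in runs]
        checks["voxel_size"] = [(r.run_id, _normalize_value(r.voxel_size)) for r in runs]

    mismatches: list[MetadataMismatch] = []
    for name, pairs in checks.items():
        counts = Counter(v for _, v in pairs)
        ranked = counts.most_common()
        if len(ranked) == 1:
            continue  # everyone agrees
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            mismatches.append(MetadataMismatch(field_name=name, majority_value=None,
                                               deviants=list(pairs)))
            continue
        majority = ranked[0][0]
        deviants = [(rid, v) for rid, v in pairs if v != majority]
        mismatches.append(MetadataMismatch(field_name=name, majority_value=majority,
                                           deviants=deviants))
    return mismatches
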