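"""Per-image heterogeneity scoring: trimmed voxel variance, heatmaps.

The score for one (mouse, day) image is the variance of the distal-ROI
voxel PDFF values after discarding values above the 90th percentile.
Trimming is one-sided (upper) only: the percentile cut exists to remove
extreme high outliers, while low PDFF values are the disease signal and
must never be removed.  Sample variance (n-1 denominator) and linear
interpolation between order statistics are the fixed conventions and are
recorded in every exported record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateROIError,
    FlatTrajectoryError,
    ShapeMismatchError,
    ValidationError,
)
from .io import CohortTable, HeterogeneityRecord, PDFFVolume, ROIMask
from .phantom import StudyDataset
from .segmentation import (
    DEFAULT_F_HIGH,
    DEFAULT_F_LOW,
    DEFAULT_FLAT_TOL,
    DEFAULT_SMOOTH_WINDOW,
    RegionBoundaries,
    axial_mean_trajectory,
    detect_regions,
    extract_region_mask,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeterogeneityParams:
    """Scoring conventions for the trimmed voxel variance."""

    trim_percentile: float = 90.0
    variance_convention: str = "sample"

    def __post_init__(self):
        if not 0.0 < self.trim_percentile <= 100.0:
            raise ValidationError("trim_percentile must lie in (0, 100]")
        if self.variance_convention not in ("sample", "population"):
            raise ValidationError("variance_convention must be 'sample' or 'population'")

    @property
    def ddof(self) -> int:
        return 1 if self.variance_convention == "sample" else 0


def roi_values(volume: PDFFVolume, mask: ROIMask) -> np.ndarray:
    """In-mask voxel values, one per member voxel, in raster (C) order."""
    if volume.values.shape != mask.membership.shape:
        raise ShapeMismatchError(
            f"volume shape {volume.values.shape} != mask shape {mask.membership.shape}"
        )
    if mask.n_voxels == 0:
        raise ValidationError("mask is empty")
    vals = volume.values[mask.membership]
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite PDFF value inside the mask")
    return vals


def trim_values(values: np.ndarray, trim_percentile: float) -> tuple[np.ndarray, float]:
    """Retain values at/below the percentile threshold (linear interpolation)."""
    values = np.asarray(values, dtype=float)
    threshold = float(np.percentile(values, trim_percentile, method="linear"))
    return values[values <= threshold], threshold


def trimmed_variance(values, params: HeterogeneityParams = HeterogeneityParams()) -> float:
    """Variance of the values retained after upper-percentile trimming.

    Invariant to input ordering; equals the plain variance when the trim
    percentile is 100 (the threshold is then the maximum, so nothing is
    removed).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        values = values.ravel()
    if values.size < 2:
        raise DegenerateROIError(
            f"need >= 2 voxel values, got {values.size}", values.size, values.size
        )
    retained, _ = trim_values(values, params.trim_percentile)
    if retained.size < 2:
        raise DegenerateROIError(
            f"only {retained.size} of {values.size} values retained after trimming",
            values.size,
            retained.size,
        )
    return float(np.var(retained, ddof=params.ddof))


def score_image(
    volume: PDFFVolume,
    mask: ROIMask,
    params: HeterogeneityParams = HeterogeneityParams(),
    *,
    bounds: RegionBoundaries | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    f_low: float = DEFAULT_F_LOW,
    f_high: float = DEFAULT_F_HIGH,
    flat_tol: float = DEFAULT_FLAT_TOL,
) -> dict:
    """Score one image: segment the distal region and trim-score it.

    When the trajectory is flat (late disease collapses the contrast
    between the zones) the whole mask is scored as a single region.
    Returns score, untrimmed distal mean PDFF, and audit counts.
    """
    volume.validate_range(mask)
    if bounds is None:
        traj = axial_mean_trajectory(volume, mask)
        try:
            bounds = detect_regions(traj, smooth_window, f_low, f_high, flat_tol)
        except FlatTrajectoryError as exc:
            log.warning("flat trajectory (%s); scoring whole mask", exc)
            bounds = None
    if bounds is None:
        distal = mask
    else:
        distal = extract_region_mask(mask, bounds, "distal")
    values = roi_values(volume, distal)
    retained, _ = trim_values(values, params.trim_percentile)
    score = trimmed_variance(values, params)
    return {
        "score": score,
        "mean_pdff": float(values.mean()),
        "n_voxels_total": int(values.size),
        "n_voxels_retained": int(retained.size),
        "trim_percentile": params.trim_percentile,
        "bounds": bounds,
    }


def score_dataset(
    dataset: StudyDataset,
    params: HeterogeneityParams = HeterogeneityParams(),
    *,
    bounds: dict | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    f_low: float = DEFAULT_F_LOW,
    f_high: float = DEFAULT_F_HIGH,
    flat_tol: float = DEFAULT_FLAT_TOL,
) -> CohortTable:
    """One heterogeneity record per manifest row.

    Per-row failures (degenerate ROI, invalid values) are logged and
    yield an absent record, never a silent zero.  ``bounds`` may map
    (mouse_id, day) to precomputed :class:`RegionBoundaries`.
    """
    records = []
    for row, volume, mask in dataset.iter_images():
        key = (row.mouse_id, row.day)
        if volume is None or mask is None:
            log.warning("manifest row %s has no image; skipped", key)
            continue
        try:
            res = score_image(
                volume,
                mask,
                params,
                bounds=None if bounds is None else bounds.get(key),
                smooth_window=smooth_window,
                f_low=f_low,
                f_high=f_high,
                flat_tol=flat_tol,
            )
        except (DegenerateROIError, ValidationError) as exc:
            log.warning("scoring failed for %s: %s", key, exc)
            continue
        records.append(
            HeterogeneityRecord(
                mouse_id=row.mouse_id,
                group=row.group,
                day=int(row.day),
                score=res["score"],
                n_voxels_total=res["n_voxels_total"],
                n_voxels_retained=res["n_voxels_retained"],
                trim_percentile=res["trim_percentile"],
                mean_pdff=res["mean_pdff"],
            )
        )
    return CohortTable.from_records(records)


@dataclass(frozen=True)
class HeatmapSlice:
    """A single axial slice for pseudo-colour display.

    In-mask pixels carry the raw PDFF values; out-of-mask pixels are NaN
    (transparent), never 0, since 0 is a valid PDFF.  The colour scale is
    pinned at 0 and 100 regardless of the data range.
    """

    values: np.ndarray
    slice_index: int
    vmin: float = 0.0
    vmax: float = 100.0


def heatmap_slice(volume: PDFFVolume, mask: ROIMask, slice_index: int) -> HeatmapSlice:
    """2D in-mask PDFF map of one bone-axis slice."""
    vals = np.moveaxis(volume.values, volume.bone_axis, 0)
    memb = np.moveaxis(mask.membership, mask.bone_axis, 0)
    if vals.shape != memb.shape:
        raise ShapeMismatchError("volume and mask shapes differ")
    if not 0 <= slice_index < vals.shape[0]:
        raise ValidationError(f"slice {slice_index} outside the volume")
    m = memb[slice_index]
    if not m.any():
        raise ValidationError(f"slice {slice_index} has no mask voxels")
    out = np.full(m.shape, np.nan)
    out[m] = vals[slice_index][m]
    return HeatmapSlice(out, slice_index=int(slice_index))
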