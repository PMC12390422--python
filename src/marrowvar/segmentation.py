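"""Axial mean trajectory and proximal/transition/distal splitting.

The per-slice mean PDFF along the bone rises from a low hematopoietic
plateau proximally to a fat-rich plateau distally.  Region boundaries are
found with a plateau-fraction rule: smooth the trajectory, estimate the
two plateau levels from its ends, and place the proximal/transition and
transition/distal boundaries at the first crossings of fractional cuts
between the levels.  Only relative levels matter, so the rule is
invariant to adding a constant to the whole trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FlatTrajectoryError, ShapeMismatchError, ValidationError
from .io import PDFFVolume, ROIMask

#: Default plateau-fraction rule parameters.
DEFAULT_SMOOTH_WINDOW = 3
DEFAULT_F_LOW = 0.25
DEFAULT_F_HIGH = 0.75
#: Plateau gap (percent PDFF) below which no transition is declared.
DEFAULT_FLAT_TOL = 1.0


@dataclass
class AxialTrajectory:
    """Per-slice mean PDFF along the bone axis, mask-restricted.

    Slices with no mask voxels are omitted entirely (rather than
    zero-filled) so they cannot bias the plateau estimates.
    """

    slice_index: np.ndarray
    mean_pdff: np.ndarray
    n_voxels: np.ndarray

    def __post_init__(self):
        self.slice_index = np.asarray(self.slice_index, dtype=int)
        self.mean_pdff = np.asarray(self.mean_pdff, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        if not (len(self.slice_index) == len(self.mean_pdff) == len(self.n_voxels)):
            raise ValidationError("trajectory arrays must share a length")
        if np.any(np.diff(self.slice_index) <= 0):
            raise ValidationError("slice indices must be strictly increasing")
        if np.any(self.n_voxels < 1):
            raise ValidationError("every listed slice needs >= 1 mask voxel")

    def __len__(self) -> int:
        return len(self.slice_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slice_index": self.slice_index,
                "mean_pdff": self.mean_pdff,
                "n_voxels": self.n_voxels,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RegionBoundaries:
    """Half-open region boundaries along the bone axis (0-based slices).

    proximal = [mask start, p_end), transition = [p_end, d_start),
    distal = [d_start, mask end].
    """

    p_end: int
    d_start: int

    def __post_init__(self):
        if self.d_start < self.p_end:
            raise ValidationError("region boundaries must satisfy p_end <= d_start")


def axial_mean_trajectory(volume: PDFFVolume, mask: ROIMask) -> AxialTrajectory:
    """Arithmetic mean of in-mask PDFF per bone-axis slice."""
    if volume.values.shape != mask.membership.shape:
        raise ShapeMismatchError(
            f"volume shape {volume.values.shape} != mask shape {mask.membership.shape}"
        )
    if mask.n_voxels == 0:
        raise ValidationError("mask is empty")
    vals = np.moveaxis(volume.values, volume.bone_axis, 0)
    memb = np.moveaxis(mask.membership, volume.bone_axis, 0)
    idx, means, counts = [], [], []
    for s in range(vals.shape[0]):
        m = memb[s]
        n = int(m.sum())
        if n == 0:
            continue
        idx.append(s)
        means.append(float(vals[s][m].mean()))
        counts.append(n)
    return AxialTrajectory(np.array(idx), np.array(means), np.array(counts))


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated at the edges."""
    half_l = (window - 1) // 2
    half_r = window // 2
    out = np.empty_like(y, dtype=float)
    for i in range(len(y)):
        lo = max(0, i - half_l)
        hi = min(len(y), i + half_r + 1)
        out[i] = y[lo:hi].mean()
    return out


def detect_regions(
    traj: AxialTrajectory,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    f_low: float = DEFAULT_F_LOW,
    f_high: float = DEFAULT_F_HIGH,
    flat_tol: float = DEFAULT_FLAT_TOL,
) -> RegionBoundaries:
    """Plateau-fraction boundary rule on a smoothed trajectory.

    Plateau levels Lp/Ld are the means of the first/last ``smooth_window``
    smoothed values.  The proximal region ends at the first slice whose
    smoothed value crosses ``Lp + f_low*(Ld - Lp)`` (toward the distal
    level); the distal region starts at the first slice at/after it
    crossing the ``f_high`` cut.  Boundaries are clamped so that the
    ordering invariants hold and the distal region is non-empty.

    Raises :class:`FlatTrajectoryError` when the plateau gap is below
    ``flat_tol`` — the caller may then treat the whole mask as one region.
    """
    if len(traj) < 3:
        raise ValidationError("trajectory must span at least 3 slices")
    if not 0.0 < f_low < f_high < 1.0:
        raise ValidationError("need 0 < f_low < f_high < 1")
    if smooth_window < 1:
        raise ValidationError("smooth_window must be >= 1")
    s = _smooth(traj.mean_pdff, smooth_window)
    k = min(smooth_window, len(s))
    lp = float(s[:k].mean())
    ld = float(s[-k:].mean())
    gap = ld - lp
    if abs(gap) < flat_tol:
        raise FlatTrajectoryError(
            f"plateau gap {gap:.3g} below tolerance {flat_tol}: no transition detectable",
            gap,
        )
    low_cut = lp + f_low * gap
    high_cut = lp + f_high * gap
    sign = 1.0 if gap > 0 else -1.0
    n = len(s)
    crossed_low = np.nonzero(sign * (s - low_cut) > 0)[0]
    p_pos = int(crossed_low[0]) if crossed_low.size else n - 1
    crossed_high = np.nonzero((np.arange(n) >= p_pos) & (sign * (s - high_cut) > 0))[0]
    d_pos = int(crossed_high[0]) if crossed_high.size else n - 1
    d_pos = min(max(d_pos, p_pos), n - 1)  # monotone repair, distal non-empty
    return RegionBoundaries(
        p_end=int(traj.slice_index[p_pos]), d_start=int(traj.slice_index[d_pos])
    )


def extract_region_mask(mask: ROIMask, bounds: RegionBoundaries, region: str) -> ROIMask:
    """Keep exactly the member voxels whose slice falls in one region.

    The three regions partition the mask's voxels.
    """
    if region not in ("proximal", "transition", "distal"):
        raise ValidationError(f"unknown region {region!r}")
    memb = np.moveaxis(mask.membership, mask.bone_axis, 0)
    slice_ids = np.arange(memb.shape[0])
    if region == "proximal":
        keep = slice_ids < bounds.p_end
    elif region == "transition":
        keep = (slice_ids >= bounds.p_end) & (slice_ids < bounds.d_start)
    else:
        keep = slice_ids >= bounds.d_start
    out = memb & keep[:, None, None]
    if not out.any():
        raise ValidationError(f"{region} region contains no mask voxels")
    return ROIMask(np.moveaxis(out, 0, mask.bone_axis), bone_axis=mask.bone_axis)
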