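"""Synthetic longitudinal tibia PDFF phantoms.

The mouse tibia carries hematopoietically active (low-fat) marrow
proximally and fat-rich marrow (~50% PDFF) distally, with a transition
zone between them.  Myelofibrosis that fails therapy collapses distal
PDFF — mean and voxel heterogeneity — toward zero over weeks, while
effective therapy lets both recover toward the healthy baseline.  The
phantoms here reproduce that statistical structure (not anatomy): a
straight cylindrical marrow tube with three axial zones, voxel values
drawn from a Beta law rescaled to [0, 100] and parameterised by the
target mean and variance, and simple disease-course kinetics.

Voxel-value law: a Beta distribution scaled to [0, 100] respects the
PDFF range exactly, so the nominal moments are achieved without any
truncation bias and range clipping never triggers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import REGION_CODES, PDFFVolume, ROIMask

#: Mean PDFF of healthy distal tibia marrow (percent): roughly half fat.
HEALTHY_MEAN_PDFF = 50.0

#: Generating distal voxel variance (percent^2) for healthy phantoms.
#: Calibrated so that the full pipeline (zone segmentation + 90th-percentile
#: trim + sample variance) returns a mean heterogeneity score of ~49
#: percent^2, the healthy-group average score of the study this emulates.
#: Upper trimming shrinks variance by ~x0.7, hence the generating value
#: sits well above 49.  Calibration, not ground truth.
HEALTHY_DISTAL_VARIANCE = 66.0

#: Mean / variance of the hematopoietic proximal zone (percent, percent^2).
PROXIMAL_MEAN_PDFF = 5.0
PROXIMAL_VARIANCE = 4.0


@dataclass(frozen=True)
class DiseaseCourseSpec:
    """Deterministic per-group disease-course kinetics.

    Distal mean PDFF and target voxel variance relax exponentially from
    their day-0 baselines (``mu0``, ``v0``) toward asymptotes
    (``mu_floor``, ``v_floor``): collapse toward ~0 for non-responders,
    recovery toward healthy values for responders.  ``day0_inflation``
    multiplies the day-0 variance only, modelling the disordered marrow
    just after irradiation and transplant.  ``dropout_prob`` is the
    per-(mouse, post-baseline day) probability of a missing scan.
    """

    group_kind: str
    days: tuple[int, ...] = (0,)
    mu0: float = HEALTHY_MEAN_PDFF
    mu_floor: float = HEALTHY_MEAN_PDFF
    decay_rate: float = 0.0
    v0: float = HEALTHY_DISTAL_VARIANCE
    v_floor: float = HEALTHY_DISTAL_VARIANCE
    v_decay_rate: float = 0.0
    day0_inflation: float = 1.0
    dropout_prob: float = 0.0
    label: str | None = None

    def __post_init__(self):
        if self.group_kind not in ("healthy", "nonresponder", "responder"):
            raise ValidationError(f"unknown group_kind {self.group_kind!r}")
        days = tuple(int(d) for d in self.days)
        object.__setattr__(self, "days", days)
        if not days or days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("days must be strictly increasing and start at 0")
        if not 0.0 <= self.mu_floor <= 100.0 or not 0.0 <= self.mu0 <= 100.0:
            raise ValidationError("mean PDFF parameters must lie in [0, 100]")
        if self.group_kind == "nonresponder" and self.mu_floor > self.mu0:
            raise ValidationError("nonresponder course requires mu_floor <= mu0")
        if self.group_kind == "responder" and self.mu_floor < self.mu0:
            raise ValidationError("responder course recovers upward: mu_floor >= mu0")
        if self.v0 <= 0 or self.v_floor < 0:
            raise ValidationError("v0 must be > 0 and v_floor >= 0")
        if self.decay_rate < 0 or self.v_decay_rate < 0:
            raise ValidationError("decay rates must be non-negative")
        if self.day0_inflation <= 0:
            raise ValidationError("day0_inflation must be positive")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValidationError("dropout_prob must lie in [0, 1)")

    @property
    def group(self) -> str:
        return self.label if self.label is not None else self.group_kind


def healthy_course(days: Sequence[int] = (0,), *, label: str = "healthy") -> DiseaseCourseSpec:
    """Healthy controls: constant mean and variance at the healthy baseline."""
    return DiseaseCourseSpec(group_kind="healthy", days=tuple(days), label=label)


def nonresponder_course(
    days: Sequence[int] = (0, 64, 69, 74),
    *,
    label: str = "nonresponder",
    dropout_prob: float = 0.07,
) -> DiseaseCourseSpec:
    """Treatment-refractory course: distal PDFF and variance collapse.

    Day-0 variance is inflated (irradiated marrow has no settled
    composition); the rates place post-baseline scores in the single
    digits, like the published disease columns.
    """
    return DiseaseCourseSpec(
        group_kind="nonresponder",
        days=tuple(days),
        mu0=35.0,
        mu_floor=2.0,
        decay_rate=0.05,
        v0=HEALTHY_DISTAL_VARIANCE,
        v_floor=4.0,
        v_decay_rate=0.05,
        day0_inflation=2.5,
        dropout_prob=dropout_prob,
        label=label,
    )


def responder_course(
    days: Sequence[int] = (0, 64, 69, 74),
    *,
    label: str = "responder",
) -> DiseaseCourseSpec:
    """Favourable response: distal PDFF and variance recover toward healthy."""
    return DiseaseCourseSpec(
        group_kind="responder",
        days=tuple(days),
        mu0=35.0,
        mu_floor=HEALTHY_MEAN_PDFF,
        decay_rate=0.03,
        v0=HEALTHY_DISTAL_VARIANCE,
        v_floor=HEALTHY_DISTAL_VARIANCE,
        v_decay_rate=0.03,
        day0_inflation=2.5,
        label=label,
    )


def simulate_course(spec: DiseaseCourseSpec, day: int) -> tuple[float, float]:
    """Deterministic (mean PDFF, target voxel variance) at a study day."""
    day = int(day)
    if day not in spec.days:
        raise ValidationError(f"day {day} not in study schedule {spec.days}")
    if spec.group_kind == "healthy":
        return spec.mu0, spec.v0
    mu = spec.mu_floor + (spec.mu0 - spec.mu_floor) * math.exp(-spec.decay_rate * day)
    if day == 0:
        v = spec.v0 * spec.day0_inflation
    else:
        v = spec.v_floor + (spec.v0 - spec.v_floor) * math.exp(-spec.v_decay_rate * day)
    return mu, v


@dataclass(frozen=True)
class PhantomGeometry:
    """Grid geometry of a phantom tibia.

    The marrow is a tube of ``marrow_radius_voxels`` around the grid centre
    running along ``bone_axis``; the three axial zone slice counts must sum
    to the grid extent along that axis.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 30)
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.7)
    bone_axis: int = 2
    n_slices_proximal: int = 10
    n_slices_transition: int = 6
    n_slices_distal: int = 14
    marrow_radius_voxels: int = 5

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise ValidationError("grid_shape must be three positive integers")
        if not 0 <= self.bone_axis <= 2:
            raise ValidationError("bone_axis must be 0, 1 or 2")
        counts = (self.n_slices_proximal, self.n_slices_transition, self.n_slices_distal)
        if any(c < 0 for c in counts) or self.n_slices_distal < 1:
            raise ValidationError("zone slice counts must be non-negative, distal >= 1")
        if sum(counts) != self.grid_shape[self.bone_axis]:
            raise ValidationError(
                "zone slice counts must sum to the grid extent along bone_axis"
            )
        if self.marrow_radius_voxels < 1:
            raise ValidationError("marrow_radius_voxels must be >= 1")

    @property
    def n_slices(self) -> int:
        return self.grid_shape[self.bone_axis]

    @property
    def distal_start_slice(self) -> int:
        return self.n_slices_proximal + self.n_slices_transition

    def cross_section(self) -> np.ndarray:
        """Boolean in-tube mask of the two cross-sectional axes."""
        cross = [n for ax, n in enumerate(self.grid_shape) if ax != self.bone_axis]
        c0, c1 = (cross[0] - 1) / 2.0, (cross[1] - 1) / 2.0
        ii, jj = np.meshgrid(np.arange(cross[0]), np.arange(cross[1]), indexing="ij")
        return (ii - c0) ** 2 + (jj - c1) ** 2 <= self.marrow_radius_voxels**2


def _beta_feasible(mean: float, variance: float) -> bool:
    return variance < mean * (100.0 - mean)


def _draw_pdff(rng: np.random.Generator, mean: float, variance: float, size: int) -> np.ndarray:
    """Draw `size` PDFF values with the requested moments on [0, 100]."""
    if variance == 0.0:
        return np.full(size, mean)
    m = mean / 100.0
    v = variance / 10000.0
    k = m * (1.0 - m) / v - 1.0  # concentration - guaranteed > 0 by feasibility
    return 100.0 * rng.beta(m * k, (1.0 - m) * k, size=size)


def generate_volume(
    geom: PhantomGeometry,
    mean_pdff: float,
    target_variance: float,
    seed,
    *,
    proximal_mean: float = PROXIMAL_MEAN_PDFF,
    proximal_variance: float = PROXIMAL_VARIANCE,
) -> tuple[PDFFVolume, ROIMask]:
    """One phantom tibia with the requested distal-zone moments.

    Distal in-mask voxels are i.i.d. with mean ``mean_pdff`` and variance
    ``target_variance``; the proximal zone sits at a low hematopoietic
    mean; transition-zone slice means (and variances) interpolate linearly
    between the two.  Voxels outside the marrow tube are NaN sentinels.
    Identical seed -> identical volume.
    """
    if not 0.0 <= mean_pdff <= 100.0:
        raise ValidationError(f"mean PDFF {mean_pdff} outside [0, 100]")
    if target_variance < 0:
        raise ValidationError("target variance must be non-negative")
    for label, m, v in (
        ("distal", mean_pdff, target_variance),
        ("proximal", proximal_mean, proximal_variance),
    ):
        if v > 0 and not _beta_feasible(m, v):
            raise ValidationError(
                f"{label} variance {v} infeasible for a [0, 100] law at mean {m}"
            )

    rng = np.random.default_rng(seed)
    n_p, n_t = geom.n_slices_proximal, geom.n_slices_transition
    L = geom.n_slices
    slice_mean = np.empty(L)
    slice_var = np.empty(L)
    slice_mean[:n_p] = proximal_mean
    slice_var[:n_p] = proximal_variance
    for i in range(n_t):
        frac = (i + 1) / (n_t + 1)
        slice_mean[n_p + i] = proximal_mean + frac * (mean_pdff - proximal_mean)
        slice_var[n_p + i] = proximal_variance + frac * (target_variance - proximal_variance)
    slice_mean[n_p + n_t :] = mean_pdff
    slice_var[n_p + n_t :] = target_variance

    tube = geom.cross_section()
    n_in = int(tube.sum())
    canon = np.full((L,) + tube.shape, np.nan)
    labels = np.zeros((L,) + tube.shape, dtype=np.int16)
    zone_code = np.empty(L, dtype=np.int16)
    zone_code[:n_p] = REGION_CODES["proximal"]
    zone_code[n_p : n_p + n_t] = REGION_CODES["transition"]
    zone_code[n_p + n_t :] = REGION_CODES["distal"]
    for s in range(L):
        canon[s][tube] = _draw_pdff(rng, slice_mean[s], slice_var[s], n_in)
        labels[s][tube] = zone_code[s]

    values = np.moveaxis(canon, 0, geom.bone_axis)
    labels = np.moveaxis(labels, 0, geom.bone_axis)
    volume = PDFFVolume(values, voxel_size=geom.voxel_size, bone_axis=geom.bone_axis)
    mask = ROIMask(labels > 0, region_labels=labels, bone_axis=geom.bone_axis)
    volume.validate_range(mask)
    return volume, mask


# ---------------------------------------------------------------------------
# Longitudinal study simulation
# ---------------------------------------------------------------------------

@dataclass
class StudyDataset:
    """A simulated longitudinal study: manifest plus in-memory images.

    ``manifest`` has one row per surviving (mouse, day) with columns
    mouse_id, group, day, spleen_volume (mm^3); ``volumes``/``masks`` are
    keyed by (mouse_id, day).
    """

    manifest: pd.DataFrame
    volumes: dict = field(default_factory=dict)
    masks: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        df = pd.DataFrame(self.manifest)
        if len(df):
            if df.duplicated(subset=["mouse_id", "day"]).any():
                raise ValidationError("duplicate (mouse_id, day) manifest row")
            for key in df[["mouse_id", "day"]].itertuples(index=False, name=None):
                if self.volumes and key not in self.volumes:
                    raise ValidationError(f"manifest row {key} has no volume")
                if self.masks and key not in self.masks:
                    raise ValidationError(f"manifest row {key} has no mask")
        self.manifest = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.manifest)

    def iter_images(self):
        for row in self.manifest.itertuples(index=False):
            key = (row.mouse_id, row.day)
            yield row, self.volumes.get(key), self.masks.get(key)


def _spleen_trajectory(
    rng: np.random.Generator, spec: DiseaseCourseSpec
) -> np.ndarray:
    """Spleen volumes (mm^3) over spec.days, consistent with the course.

    Splenomegaly from extramedullary hematopoiesis grows in refractory
    disease (non-decreasing), while responders lose >= 50% of baseline by
    the final day.  Lognormal baselines, mild lognormal jitter.
    """
    days = np.asarray(spec.days, dtype=float)
    if spec.group_kind == "healthy":
        base = rng.lognormal(math.log(90.0), 0.10)
        return np.full(len(days), base)
    if spec.group_kind == "nonresponder":
        base = rng.lognormal(math.log(250.0), 0.25)
        traj = base * np.exp(0.01 * days) * rng.lognormal(0.0, 0.05, len(days))
        traj[0] = base
        return np.maximum.accumulate(traj)
    # responder: exponential shrink to a 55-70% reduction at the final day
    base = rng.lognormal(math.log(400.0), 0.20)
    if len(days) == 1:
        return np.array([base])
    final_frac = rng.uniform(0.30, 0.45)
    traj = base * np.exp(math.log(final_frac) * days / days[-1])
    traj *= rng.lognormal(0.0, 0.03, len(days))
    traj[0] = base
    traj[-1] = base * final_frac
    return traj


def simulate_study(
    course_specs: Iterable[tuple[DiseaseCourseSpec, int]],
    geom: PhantomGeometry | None = None,
    seed: int = 0,
) -> StudyDataset:
    """Simulate a full cohort study: one manifest row per surviving scan.

    Each mouse gets a deterministic substream derived from
    (seed, global mouse index), so cohorts are reproducible row-for-row
    regardless of how many groups precede them.  Dropout applies only to
    post-baseline days.
    """
    geom = geom or PhantomGeometry()
    specs = list(course_specs)
    rows = []
    volumes: dict = {}
    masks: dict = {}
    g_index = 0
    for spec, n_mice in specs:
        if n_mice < 0:
            raise ValidationError("n_mice must be non-negative")
        for m in range(int(n_mice)):
            mouse_id = f"{spec.group}-{m + 1:02d}"
            ss = np.random.SeedSequence([int(seed), g_index])
            children = ss.spawn(len(spec.days) + 1)
            meta_rng = np.random.default_rng(children[0])
            spleen = _spleen_trajectory(meta_rng, spec)
            keep = np.ones(len(spec.days), dtype=bool)
            keep[1:] = meta_rng.random(len(spec.days) - 1) >= spec.dropout_prob
            for d_idx, day in enumerate(spec.days):
                if not keep[d_idx]:
                    continue
                mu, v = simulate_course(spec, day)
                vol, msk = generate_volume(geom, mu, v, children[d_idx + 1])
                volumes[(mouse_id, day)] = vol
                masks[(mouse_id, day)] = msk
                rows.append(
                    {
                        "mouse_id": mouse_id,
                        "group": spec.group,
                        "day": int(day),
                        "spleen_volume": float(spleen[d_idx]),
                    }
                )
            g_index += 1
    manifest = pd.DataFrame(rows, columns=["mouse_id", "group", "day", "spleen_volume"])
    provenance = {
        "seed": int(seed),
        "geometry": dataclasses.asdict(geom),
        "courses": [
            {"spec": dataclasses.asdict(spec), "n_mice": int(n)} for spec, n in specs
        ],
    }
    return StudyDataset(manifest, volumes, masks, provenance)


def default_study_specs(
    *,
    n_healthy: int = 15,
    n_disease1: int = 17,
    n_disease2: int = 12,
    dropout_prob: float = 0.07,
) -> list[tuple[DiseaseCourseSpec, int]]:
    """The default simulated study: cohort sizes and scan schedules mirror
    the three groups of the study this package emulates."""
    return [
        (healthy_course(label="healthy"), n_healthy),
        (nonresponder_course((0, 64, 69, 74), label="disease1", dropout_prob=dropout_prob), n_disease1),
        (nonresponder_course((0, 55, 77, 93), label="disease2", dropout_prob=dropout_prob), n_disease2),
    ]
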