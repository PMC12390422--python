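"""Volumes, masks, cohort tables and their on-disk forms.

PDFF volumes and marrow masks travel as NIfTI (via nibabel); cohort score
tables use a long CSV schema (group, mouse_id, day, score) that mirrors the
per-mouse / per-scan-date layout of the published variance table, which is
bundled as a fixture.  Mouse numbering in that table restarts per cohort,
so record uniqueness is enforced on (group, mouse_id, day).
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ShapeMismatchError, ValidationError

REGION_CODES = {"proximal": 1, "transition": 2, "distal": 3}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}

#: Study-schedule days of the bundled fixture, per group.
FIXTURE_DAYS = {
    "healthy": (0,),
    "disease1": (0, 64, 69, 74),
    "disease2": (0, 55, 77, 93),
}


@dataclass
class PDFFVolume:
    """A 3D proton-density-fat-fraction map in percent units.

    ``bone_axis`` indexes the grid axis running along the bone, with slice
    index ascending proximal -> distal.  Voxels outside any marrow mask may
    carry NaN as a sentinel non-value.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    bone_axis: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("PDFF volume must be a 3D grid")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size must be three positive lengths (mm)")
        if not 0 <= self.bone_axis <= 2:
            raise ValidationError("bone_axis must be 0, 1 or 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def validate_range(self, mask: "ROIMask | None" = None) -> None:
        """Reject in-mask values outside [0, 100] or non-finite.

        PDFF is a percentage by definition; values outside the range are a
        data defect and are never silently clipped.
        """
        if mask is None:
            vals = self.values[np.isfinite(self.values)]
        else:
            if mask.membership.shape != self.values.shape:
                raise ShapeMismatchError(
                    f"mask shape {mask.membership.shape} != volume shape {self.values.shape}"
                )
            vals = self.values[mask.membership]
            if not np.all(np.isfinite(vals)):
                raise ValidationError("non-finite PDFF value inside the mask")
        if vals.size and (vals.min() < 0.0 or vals.max() > 100.0):
            bad = vals[(vals < 0.0) | (vals > 100.0)][0]
            raise ValidationError(
                f"PDFF value {bad:g} outside the valid range [0, 100]"
            )


@dataclass
class ROIMask:
    """Binary marrow mask, optionally carrying per-voxel region labels.

    ``region_labels`` uses 0 outside the mask and the codes in
    :data:`REGION_CODES` (1 proximal, 2 transition, 3 distal) inside it.
    """

    membership: np.ndarray
    region_labels: np.ndarray | None = None
    bone_axis: int = 0

    def __post_init__(self):
        self.membership = np.asarray(self.membership).astype(bool)
        if self.membership.ndim != 3:
            raise ValidationError("ROI mask must be a 3D grid")
        if self.region_labels is not None:
            self.region_labels = np.asarray(self.region_labels, dtype=np.int16)
            if self.region_labels.shape != self.membership.shape:
                raise ShapeMismatchError("region label grid shape differs from mask")
            if np.any((self.region_labels != 0) != self.membership):
                raise ValidationError("region labels must cover exactly the mask")

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    def region(self, name: str) -> "ROIMask":
        """Sub-mask of one labelled region (requires labels)."""
        if self.region_labels is None:
            raise ValidationError("mask carries no region labels")
        code = REGION_CODES[name]
        return ROIMask(self.region_labels == code, bone_axis=self.bone_axis)


@dataclass(frozen=True)
class HeterogeneityRecord:
    """One trimmed-variance heterogeneity score for one (mouse, day)."""

    mouse_id: int | str
    group: str
    day: int
    score: float
    n_voxels_total: int | None = None
    n_voxels_retained: int | None = None
    trim_percentile: float | None = None
    mean_pdff: float | None = None

    def __post_init__(self):
        if self.score < 0:
            raise ValidationError("heterogeneity score must be non-negative")
        if self.n_voxels_total is not None and self.n_voxels_retained is not None:
            if not 0 < self.n_voxels_retained <= self.n_voxels_total:
                raise ValidationError("0 < n_voxels_retained <= n_voxels_total required")


_REQUIRED_COLS = ("group", "mouse_id", "day", "score")


@dataclass
class CohortTable:
    """Collection of heterogeneity records: the study's score table.

    Missing (mouse, day) cells are simply absent rows, matching the
    published table where empty cells mark mice that did not survive.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in _REQUIRED_COLS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns {missing}")
        df["day"] = df["day"].astype(int)
        df["score"] = df["score"].astype(float)
        if (df["score"] < 0).any():
            raise ValidationError("negative heterogeneity score in cohort table")
        dup = df.duplicated(subset=["group", "mouse_id", "day"])
        if dup.any():
            key = df.loc[dup, ["group", "mouse_id", "day"]].iloc[0].tolist()
            raise ValidationError(f"duplicate (group, mouse_id, day) record {key}")
        self.data = df.sort_values(["group", "mouse_id", "day"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def from_records(cls, records: Iterable[HeterogeneityRecord]) -> "CohortTable":
        rows = [dataclasses.asdict(r) for r in records]
        if not rows:
            return cls(pd.DataFrame(columns=list(_REQUIRED_COLS)))
        df = pd.DataFrame(rows)
        return cls(df.dropna(axis="columns", how="all"))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def n_mice(self, group: str) -> int:
        return int(self.data.loc[self.data["group"] == group, "mouse_id"].nunique())

    def scores(self, group: str, day: int | None = None) -> np.ndarray:
        sel = self.data["group"] == group
        if day is not None:
            sel &= self.data["day"] == day
        return self.data.loc[sel, "score"].to_numpy()

    def to_wide(self, group: str) -> pd.DataFrame:
        """Mice x scan-days layout, NaN where a cell is missing."""
        sub = self.data[self.data["group"] == group]
        return sub.pivot(index="mouse_id", columns="day", values="score")

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CohortTable":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ValidationError(f"cannot parse cohort table {path}: {exc}") from exc
        return cls(df)


# ---------------------------------------------------------------------------
# NIfTI volume / mask IO
# ---------------------------------------------------------------------------

def _affine(voxel_size: Sequence[float]) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def write_volume(volume: PDFFVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine(volume.voxel_size))
    img.header.set_zooms(volume.voxel_size)
    img.header["descrip"] = f"PDFF percent; bone_axis={volume.bone_axis}".encode()
    nib.save(img, str(path))


def read_volume(path: str | Path) -> PDFFVolume:
    try:
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:
        raise ValidationError(f"cannot read PDFF volume {path}: {exc}") from exc
    if values.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got shape {values.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    descrip = img.header["descrip"].tobytes().decode(errors="replace")
    m = re.search(r"bone_axis=(\d)", descrip)
    bone_axis = int(m.group(1)) if m else 0
    return PDFFVolume(values, voxel_size=zooms, bone_axis=bone_axis)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    if mask.region_labels is not None:
        data = mask.region_labels.astype(np.int16)
    else:
        data = mask.membership.astype(np.int16)
    img = nib.Nifti1Image(data, np.eye(4))
    img.header["descrip"] = f"marrow ROI; bone_axis={mask.bone_axis}".encode()
    nib.save(img, str(path))


def read_mask(path: str | Path) -> ROIMask:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise ValidationError(f"cannot read ROI mask {path}: {exc}") from exc
    descrip = img.header["descrip"].tobytes().decode(errors="replace")
    m = re.search(r"bone_axis=(\d)", descrip)
    bone_axis = int(m.group(1)) if m else 0
    data = np.asarray(data, dtype=np.int16)
    labels = data if np.any(data > 1) else None
    return ROIMask(data > 0, region_labels=labels, bone_axis=bone_axis)


# ---------------------------------------------------------------------------
# Bundled fixture
# ---------------------------------------------------------------------------

def load_table1_fixture() -> CohortTable:
    """Load the bundled per-mouse PDFF variance table.

    Three groups: 15 healthy mice scanned once at day 0; 17 disease-1 mice
    over days 0/64/69/74; 12 disease-2 mice over days 0/55/77/93.  Cells
    where a mouse did not survive have no record.
    """
    ref = resources.files("marrowvar.data") / "table1_variances.csv"
    try:
        with resources.as_file(ref) as p:
            table = CohortTable.read_csv(p)
    except (FileNotFoundError, ValidationError) as exc:
        raise ValidationError(f"fixture table unavailable: {exc}") from exc
    for group, days in FIXTURE_DAYS.items():
        extra = set(table.data.loc[table.data["group"] == group, "day"]) - set(days)
        if extra:
            raise ValidationError(f"fixture group {group} has unexpected days {extra}")
    return table


# ---------------------------------------------------------------------------
# Result bundle
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def write_results(
    out_dir: str | Path,
    *,
    cohort: CohortTable | None = None,
    stats: Mapping | None = None,
    fits: pd.DataFrame | None = None,
    group_lines: pd.DataFrame | None = None,
    quartiles: pd.DataFrame | None = None,
    classification: pd.DataFrame | None = None,
    run_manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write the analysis bundle: CSVs for tables, JSON for test results.

    Row order is deterministic (group, mouse_id, day) regardless of the
    order results were computed in.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if cohort is not None:
        paths["scores"] = out / "scores.csv"
        cohort.write_csv(paths["scores"])  # CohortTable keeps sorted order
    if stats is not None:
        paths["stats"] = out / "stats.json"
        write_json(stats, paths["stats"])
    for name, df, sort_cols in (
        ("regressions", fits, ["group", "mouse_id"]),
        ("group_lines", group_lines, ["group"]),
        ("quartiles", quartiles, ["group", "day"]),
        ("classification", classification, ["group", "mouse_id"]),
    ):
        if df is not None:
            cols = [c for c in sort_cols if c in df.columns]
            ordered = df.sort_values(cols, kind="mergesort") if cols else df
            paths[name] = out / f"{name}.csv"
            ordered.to_csv(paths[name], index=False)
    if run_manifest is not None:
        paths["run_manifest"] = out / "run_manifest.json"
        write_json(run_manifest, paths["run_manifest"])
    return paths
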