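"""End-to-end runs: simulate -> segment -> score -> infer -> report.

Three modes:

* ``simulate`` — generate a phantom study, score it, run inference;
* ``analyze``  — score an existing study from a manifest CSV referencing
  NIfTI volumes/masks;
* ``fixture``  — run inference directly on the bundled per-mouse
  variance table (touches no image data).

A run is fully determined by (config, seed): identical inputs produce
byte-identical score tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .cohort import CohortHeterogeneityModel
from .errors import ValidationError
from .group_stats import MouseCourse
from .heterogeneity import HeterogeneityParams, score_dataset
from .phantom import PhantomGeometry, StudyDataset, default_study_specs, simulate_study
from .segmentation import axial_mean_trajectory

log = logging.getLogger(__name__)

MODES = ("simulate", "analyze", "fixture")


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    mode: str = "fixture"
    out_dir: str = "marrowvar_run"
    seed: int = 0
    manifest: str | None = None  # analyze mode input
    scores: str | None = None  # pre-computed cohort CSV (report-style runs)
    n_perm: int = 10_000
    alpha: float = 0.05
    pca_components: int = 2
    exhaustive_limit: int = 200_000
    trim_percentile: float = 90.0
    variance_convention: str = "sample"
    write_images: bool = False
    log_level: str = "INFO"
    phantom: dict = field(default_factory=dict)  # cohort sizes / dropout overrides

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}")
        if self.mode == "analyze" and not (self.manifest or self.scores):
            raise ValidationError("analyze mode needs a manifest or scores path")
        if self.mode in ("simulate",) and self.seed is None:
            raise ValidationError("simulate mode requires a seed")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_study(dataset: StudyDataset, out_dir: str | Path) -> Path:
    """Write a simulated study as NIfTI volumes/masks plus a manifest CSV."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for row, volume, mask in dataset.iter_images():
        stem = f"{row.mouse_id}_day{row.day:03d}"
        vpath = out / "images" / f"{stem}_pdff.nii"
        mpath = out / "images" / f"{stem}_mask.nii"
        mio.write_volume(volume, vpath)
        mio.write_mask(mask, mpath)
        rows.append(
            {
                "mouse_id": row.mouse_id,
                "group": row.group,
                "day": row.day,
                "volume_path": str(vpath.relative_to(out)),
                "mask_path": str(mpath.relative_to(out)),
                "spleen_volume": row.spleen_volume,
            }
        )
    manifest_path = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def read_study(manifest_path: str | Path) -> StudyDataset:
    """Load a study from a manifest CSV of NIfTI paths."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"mouse_id", "group", "day", "volume_path", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns {sorted(missing)}")
    root = manifest_path.parent
    volumes, masks = {}, {}
    for row in df.itertuples(index=False):
        key = (row.mouse_id, int(row.day))
        volume = mio.read_volume(root / row.volume_path)
        mask = mio.read_mask(root / row.mask_path)
        if volume.values.shape != mask.membership.shape:
            raise ValidationError(f"volume/mask shape mismatch for {key}")
        volumes[key] = volume
        masks[key] = mask
    keep = [c for c in ("mouse_id", "group", "day", "spleen_volume") if c in df.columns]
    manifest = df[keep].copy()
    manifest["day"] = manifest["day"].astype(int)
    return StudyDataset(manifest, volumes, masks, {"manifest_path": str(manifest_path)})


def _build_courses(dataset: StudyDataset, table: mio.CohortTable) -> list[MouseCourse]:
    """Per-mouse longitudinal courses joining scores with spleen volumes."""
    merged = table.data.merge(
        dataset.manifest, on=["mouse_id", "group", "day"], how="left"
    )
    courses = []
    for (group, mouse), sub in merged.groupby(["group", "mouse_id"]):
        sub = sub.sort_values("day")
        spleen = (
            sub["spleen_volume"].to_numpy()
            if "spleen_volume" in sub and sub["spleen_volume"].notna().all()
            else None
        )
        courses.append(
            MouseCourse(
                mouse_id=str(mouse),
                days=sub["day"].to_numpy(),
                mean_pdff=sub["mean_pdff"].to_numpy() if "mean_pdff" in sub else None,
                score=sub["score"].to_numpy(),
                spleen_volume=spleen,
                group=group,
            )
        )
    return courses


def _simulated_dataset(config: RunConfig) -> StudyDataset:
    ph = dict(config.phantom)
    geom = PhantomGeometry(**ph.pop("geometry")) if "geometry" in ph else None
    specs = default_study_specs(**ph)
    return simulate_study(specs, geom=geom, seed=config.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Execute one full run; returns output paths and headline numbers."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = HeterogeneityParams(
        trim_percentile=config.trim_percentile,
        variance_convention=config.variance_convention,
    )

    dataset = None
    if config.mode == "fixture":
        table = mio.load_table1_fixture()
    elif config.scores is not None:
        table = mio.CohortTable.read_csv(config.scores)
    else:
        if config.mode == "simulate":
            log.info("simulating phantom study (seed=%s)", config.seed)
            dataset = _simulated_dataset(config)
            if config.write_images:
                write_study(dataset, out)
        else:
            log.info("loading study from %s", config.manifest)
            dataset = read_study(config.manifest)
        table = score_dataset(dataset, params)
        traj_dir = out / "trajectories"
        traj_dir.mkdir(exist_ok=True)
        for row, volume, mask in dataset.iter_images():
            traj = axial_mean_trajectory(volume, mask)
            traj.to_csv(traj_dir / f"{row.mouse_id}_day{row.day:03d}.csv")

    courses = _build_courses(dataset, table) if dataset is not None else None
    model = CohortHeterogeneityModel(table, courses=courses)
    results = model.fit(
        n_perm=config.n_perm,
        seed=config.seed,
        alpha=config.alpha,
        pca_components=config.pca_components,
        exhaustive_limit=config.exhaustive_limit,
    )

    try:
        pkg_version = version("marrowvar")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    run_manifest = {
        "config": dataclasses.asdict(config),
        "package_version": pkg_version,
        "n_records": len(table),
        "groups": {g: int(table.n_mice(g)) for g in table.groups},
    }
    paths = mio.write_results(
        out,
        cohort=table,
        stats=results.stats_dict(),
        fits=results.fits_frame(),
        group_lines=results.group_lines_frame(),
        quartiles=results.quartiles,
        classification=results.classification,
        run_manifest=run_manifest,
    )
    (out / "summary.txt").write_text(results.summary() + "\n")
    headline = {
        "out_dir": str(out),
        "paths": {k: str(v) for k, v in paths.items()},
        "disease_vs_healthy_p": results.disease_vs_healthy.p_value,
        "n_records": len(table),
        "summary": results.summary(),
    }
    if results.cohort_comparison is not None:
        headline["cohort_comparison_p"] = results.cohort_comparison.p_value
    return headline
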