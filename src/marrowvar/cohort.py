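"""Cohort-level model: the study's full inference in one fit.

``CohortHeterogeneityModel`` is built from a heterogeneity score table
(one trimmed-variance score per mouse per scan day); ``fit()`` runs the
study's inference battery and returns a results object with a
``summary()`` table:

* one-sided permutation test, pooled baseline (day 0) disease scores vs
  healthy scores (direction: disease > healthy, since irradiated day-0
  marrow has inflated variance);
* two-sided permutation test between the two disease cohorts over all
  per-mouse per-day scores;
* 2D PCA of per-mouse score trajectories (scan occasions as features)
  with a centroid-distance separation p-value between disease cohorts;
* 1D baseline PCA of healthy + combined disease scores, oriented so the
  disease centroid is positive;
* per-mouse OLS regressions of score on day and pooled group lines, with
  the single-time-point healthy group represented by its mean score as a
  horizontal reference;
* quartile summaries per (group, day) for violin plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .group_stats import (
    GroupLine,
    MouseCourse,
    PCAResult,
    PCASeparationResult,
    PermutationResult,
    RegressionFit,
    classify_mouse,
    combine_group_line,
    fit_mouse_regression,
    orient_scores,
    pca_embed,
    pca_separation_pvalue,
    permutation_test,
    summarize_violin,
)
from .io import CohortTable


def _child_seeds(seed: int | None, k: int) -> list[int | None]:
    if seed is None:
        return [None] * k
    ss = np.random.SeedSequence(int(seed))
    return [int(s) for s in ss.generate_state(k) % (2**31)]


class CohortHeterogeneityModel:
    """Group-level inference model over a cohort heterogeneity table."""

    def __init__(
        self,
        table: CohortTable,
        healthy_group: str = "healthy",
        disease_groups: Sequence[str] | None = None,
        baseline_day: int = 0,
        courses: list[MouseCourse] | None = None,
    ):
        self.table = table
        self.healthy_group = healthy_group
        if disease_groups is None:
            disease_groups = [g for g in table.groups if g != healthy_group]
        self.disease_groups = list(disease_groups)
        if not self.disease_groups:
            raise ValidationError("cohort table contains no disease group")
        self.baseline_day = int(baseline_day)
        self.courses = courses or []

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CohortHeterogeneityModel":
        return cls(CohortTable(df), **kwargs)

    # -- feature construction -------------------------------------------------

    def trajectory_features(self) -> tuple[pd.DataFrame, np.ndarray]:
        """Per-mouse score trajectories of the disease groups.

        The cohorts follow different calendar schedules, so features are
        aligned by scan occasion (1st..k-th scan).  Mice missing any
        occasion are dropped (no imputation).
        """
        sub = self.table.data[self.table.data["group"].isin(self.disease_groups)]
        n_occasions = min(
            sub.groupby("group")["day"].nunique().min(), sub["day"].nunique()
        )
        rows, labels, index = [], [], []
        for (group, mouse), m in sub.groupby(["group", "mouse_id"]):
            m = m.sort_values("day")
            row = np.full(n_occasions, np.nan)
            k = min(len(m), n_occasions)
            row[:k] = m["score"].to_numpy()[:k]
            rows.append(row)  # incomplete mice keep NaN and are dropped by PCA
            labels.append(group)
            index.append(f"{group}-{mouse}")
        feats = pd.DataFrame(
            rows, index=index, columns=[f"scan_{i + 1}" for i in range(n_occasions)]
        )
        return feats, np.asarray(labels)

    def baseline_features(self) -> tuple[np.ndarray, np.ndarray]:
        """Baseline-day scores of healthy + all disease mice, with labels
        'healthy' / 'disease'."""
        day0 = self.table.data[self.table.data["day"] == self.baseline_day]
        healthy = day0.loc[day0["group"] == self.healthy_group, "score"].to_numpy()
        disease = day0.loc[day0["group"].isin(self.disease_groups), "score"].to_numpy()
        values = np.concatenate([healthy, disease])
        labels = np.array(["healthy"] * healthy.size + ["disease"] * disease.size)
        return values, labels

    # -- fitting --------------------------------------------------------------

    def fit(
        self,
        n_perm: int = 10_000,
        seed: int | None = None,
        alpha: float = 0.05,
        pca_components: int = 2,
        exhaustive_limit: int = 200_000,
    ) -> "CohortHeterogeneityResults":
        seeds = _child_seeds(seed, 4)
        day0 = self.table.data[self.table.data["day"] == self.baseline_day]
        disease_day0 = day0.loc[
            day0["group"].isin(self.disease_groups), "score"
        ].to_numpy()
        healthy_scores = day0.loc[
            day0["group"] == self.healthy_group, "score"
        ].to_numpy()
        disease_vs_healthy = permutation_test(
            disease_day0,
            healthy_scores,
            sides="one_sided_greater",
            n_perm=n_perm,
            seed=seeds[0],
            exhaustive_limit=exhaustive_limit,
        )

        cohort_comparison = None
        if len(self.disease_groups) == 2:
            g1, g2 = self.disease_groups
            cohort_comparison = permutation_test(
                self.table.scores(g1),
                self.table.scores(g2),
                sides="two_sided",
                n_perm=n_perm,
                seed=seeds[1],
                exhaustive_limit=exhaustive_limit,
            )

        pca_trajectories = pca_separation = None
        if len(self.disease_groups) == 2:
            feats, labels = self.trajectory_features()
            if len(feats) >= 4 and pd.Series(labels).nunique() == 2:
                k = min(pca_components, min(feats.shape))
                pca_trajectories = pca_embed(feats, n_components=k)
                pca_separation = pca_separation_pvalue(
                    feats, labels, n_components=k, n_perm=n_perm, seed=seeds[2]
                )

        base_values, base_labels = self.baseline_features()
        pca_baseline = pca_embed(base_values[:, None], n_components=1)
        baseline_scores = orient_scores(
            pca_baseline.scores[:, 0], base_labels, positive_label="disease"
        )
        baseline_separation = pca_separation_pvalue(
            base_values[:, None], base_labels, n_components=1, n_perm=n_perm, seed=seeds[3]
        )

        fits: list[RegressionFit] = []
        fit_groups: dict[str, list[RegressionFit]] = {g: [] for g in self.disease_groups}
        for group in self.disease_groups:
            wide = self.table.to_wide(group)
            for mouse, row in wide.iterrows():
                present = row.dropna()
                if len(present) < 2:
                    continue
                course = MouseCourse(
                    mouse_id=f"{group}-{mouse}",
                    days=present.index.to_numpy(),
                    score=present.to_numpy(),
                    group=group,
                )
                f = fit_mouse_regression(course)
                fits.append(f)
                fit_groups[group].append(f)
        group_lines = [
            combine_group_line(fs, group=g) for g, fs in fit_groups.items() if fs
        ]
        healthy_reference = float(np.mean(self.table.scores(self.healthy_group)))

        classification = None
        if self.courses:
            classification = pd.DataFrame(
                [
                    {
                        "group": c.group,
                        "mouse_id": c.mouse_id,
                        "status": status,
                        "reason": reason,
                    }
                    for c in self.courses
                    for status, reason in [classify_mouse(c)]
                ]
            )

        return CohortHeterogeneityResults(
            model=self,
            disease_vs_healthy=disease_vs_healthy,
            cohort_comparison=cohort_comparison,
            pca_trajectories=pca_trajectories,
            pca_separation=pca_separation,
            pca_baseline=pca_baseline,
            baseline_scores=baseline_scores,
            baseline_labels=base_labels,
            baseline_separation=baseline_separation,
            mouse_fits=fits,
            group_lines=group_lines,
            healthy_reference=healthy_reference,
            quartiles=summarize_violin(self.table),
            classification=classification,
            config={
                "n_perm": n_perm,
                "seed": seed,
                "alpha": alpha,
                "pca_components": pca_components,
                "exhaustive_limit": exhaustive_limit,
                "baseline_day": self.baseline_day,
            },
        )


@dataclass
class CohortHeterogeneityResults:
    """Fitted cohort inference: estimates, p-values, diagnostics."""

    model: CohortHeterogeneityModel
    disease_vs_healthy: PermutationResult
    cohort_comparison: PermutationResult | None
    pca_trajectories: PCAResult | None
    pca_separation: PCASeparationResult | None
    pca_baseline: PCAResult
    baseline_scores: np.ndarray
    baseline_labels: np.ndarray
    baseline_separation: PCASeparationResult
    mouse_fits: list[RegressionFit]
    group_lines: list[GroupLine]
    healthy_reference: float
    quartiles: pd.DataFrame
    classification: pd.DataFrame | None
    config: dict = field(default_factory=dict)

    @property
    def alpha(self) -> float:
        return self.config.get("alpha", 0.05)

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.mouse_fits:
            group, _, mouse = f.mouse_id.partition("-")
            rows.append(
                {
                    "group": group,
                    "mouse_id": mouse,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "n_points": f.n_points,
                }
            )
        return pd.DataFrame(rows, columns=["group", "mouse_id", "slope", "intercept", "n_points"])

    def group_lines_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g.group, "slope": g.slope, "intercept": g.intercept, "n_fits": g.n_fits}
            for g in self.group_lines
        ]
        rows.append(
            {
                "group": self.model.healthy_group,
                "slope": 0.0,
                "intercept": self.healthy_reference,
                "n_fits": 0,
            }
        )
        return pd.DataFrame(rows, columns=["group", "slope", "intercept", "n_fits"])

    def stats_dict(self) -> dict:
        out = {
            "disease_vs_healthy": self.disease_vs_healthy.to_dict(),
            "baseline_pca_separation": self.baseline_separation.to_dict(),
            "healthy_reference_score": self.healthy_reference,
            "config": self.config,
        }
        if self.cohort_comparison is not None:
            out["cohort_comparison"] = self.cohort_comparison.to_dict()
        if self.pca_separation is not None:
            out["trajectory_pca_separation"] = self.pca_separation.to_dict()
        if self.pca_trajectories is not None:
            out["trajectory_pca_explained_variance"] = list(
                self.pca_trajectories.explained_variance_ratio
            )
        return out

    def summary(self) -> str:
        m = self.model
        t = m.table
        lines = []
        lines.append("Bone-marrow PDFF heterogeneity analysis".center(66))
        lines.append("=" * 66)
        groups = ", ".join(f"{g} (n={t.n_mice(g)})" for g in t.groups)
        lines.append(f"Groups: {groups}")
        lines.append(f"Records: {len(t)}   baseline day: {m.baseline_day}   "
                     f"alpha: {self.alpha}")
        lines.append("-" * 66)
        lines.append("Permutation tests (difference in group means)")
        dh = self.disease_vs_healthy
        lines.append(
            f"  disease (day {m.baseline_day}) > healthy : stat={dh.statistic_obs:8.3f}"
            f"  p={dh.p_value:.4f}  [{dh.n_perm} perms]"
        )
        if self.cohort_comparison is not None:
            cc = self.cohort_comparison
            g1, g2 = m.disease_groups
            lines.append(
                f"  {g1} vs {g2} (two-sided)  : stat={cc.statistic_obs:8.3f}"
                f"  p={cc.p_value:.4f}  [{cc.n_perm} perms]"
            )
        lines.append("-" * 66)
        lines.append("PCA")
        bs = self.baseline_separation
        lines.append(
            f"  baseline 1D (healthy vs disease): centroid distance="
            f"{bs.statistic_obs:.2f}  p={bs.p_value:.4f}"
        )
        if self.pca_separation is not None:
            ps = self.pca_separation
            evr = ", ".join(
                f"{v:.2f}" for v in self.pca_trajectories.explained_variance_ratio
            )
            lines.append(
                f"  trajectory {ps.n_components}D (cohort split): centroid distance="
                f"{ps.statistic_obs:.2f}  p={ps.p_value:.4f}  EVR=[{evr}]"
            )
        lines.append("-" * 66)
        lines.append("Group regression lines (score = intercept + slope * day)")
        for g in self.group_lines:
            lines.append(
                f"  {g.group:<12} slope={g.slope:8.3f}  intercept={g.intercept:8.2f}"
                f"  (mean of {g.n_fits} mouse fits)"
            )
        lines.append(
            f"  {m.healthy_group:<12} horizontal reference at mean score "
            f"{self.healthy_reference:.2f}"
        )
        if self.classification is not None and len(self.classification):
            counts = self.classification["status"].value_counts().to_dict()
            lines.append("-" * 66)
            lines.append(f"Classification: {counts}")
        lines.append("=" * 66)
        return "\n".join(lines)
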