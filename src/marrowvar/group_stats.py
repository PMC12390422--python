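"""Group-level inference on heterogeneity tables.

Permutation tests (difference in group means), PCA separation, per-mouse
OLS regressions and pooled group lines, quartile summaries for violin
plots, and disease/responder classification.  All stochastic operations
are exactly reproducible from (seed, n_perm).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ValidationError
from .io import CohortTable

SIDES = ("one_sided_greater", "one_sided_less", "two_sided")


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a label-permutation test on two groups.

    ``statistic_obs`` is mean(a) - mean(b).  For Monte-Carlo resampling
    p = (1 + #extreme) / (1 + n_perm); in exhaustive mode every distinct
    labelling is enumerated and p is the exact proportion of labellings
    as or more extreme (the observed one counts itself).
    """

    statistic_obs: float
    p_value: float
    n_perm: int
    sides: str
    seed: int | None
    exhaustive: bool
    n_a: int
    n_b: int
    degenerate: bool = False

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError("p-value must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic_obs": self.statistic_obs,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "sides": self.sides,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
            "group_sizes": [self.n_a, self.n_b],
            "degenerate": self.degenerate,
        }


def _count_extreme(stats: np.ndarray, obs: float, sides: str, eps: float) -> int:
    if sides == "one_sided_greater":
        return int(np.count_nonzero(stats >= obs - eps))
    if sides == "one_sided_less":
        return int(np.count_nonzero(stats <= obs + eps))
    return int(np.count_nonzero(np.abs(stats) >= abs(obs) - eps))


def permutation_test(
    a,
    b,
    sides: str = "two_sided",
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive_limit: int = 200_000,
) -> PermutationResult:
    """Two-group permutation test with difference-in-means statistic.

    Labels are permuted over the pooled values preserving group sizes.
    If the number of distinct labellings is at most ``exhaustive_limit``
    the null distribution is enumerated exactly; otherwise ``n_perm``
    Monte-Carlo relabellings are drawn from ``seed``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if sides not in SIDES:
        raise ValidationError(f"sides must be one of {SIDES}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    pooled = np.concatenate([a, b])
    obs = float(a.mean() - b.mean())
    if np.ptp(pooled) == 0.0:
        return PermutationResult(obs, 1.0, 0, sides, seed, True, a.size, b.size, True)
    n, na = pooled.size, a.size
    eps = 1e-12 * max(1.0, float(np.abs(pooled).max()))
    total = math.comb(n, na)
    inv_a, inv_b = 1.0 / na, 1.0 / b.size
    pooled_sum = float(pooled.sum())
    if total <= exhaustive_limit:
        sums = np.fromiter(
            (pooled[list(c)].sum() for c in itertools.combinations(range(n), na)),
            dtype=float,
            count=total,
        )
        stats = sums * inv_a - (pooled_sum - sums) * inv_b
        count = _count_extreme(stats, obs, sides, eps)
        return PermutationResult(
            obs, count / total, total, sides, seed, True, a.size, b.size
        )
    rng = np.random.default_rng(seed)
    # vectorised relabelling: argsort of uniforms is a uniform permutation
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :na]
    sums = pooled[order].sum(axis=1)
    stats = sums * inv_a - (pooled_sum - sums) * inv_b
    extreme = _count_extreme(stats, obs, sides, eps)
    p = (1.0 + extreme) / (1.0 + n_perm)
    return PermutationResult(obs, p, n_perm, sides, seed, False, a.size, b.size)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Column-centred PCA embedding (no rescaling: features share units).

    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive.  ``row_index`` identifies the complete rows that
    were embedded; rows with missing entries are dropped, never imputed.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    row_index: list = field(default_factory=list)
    n_dropped: int = 0


def pca_embed(features, n_components: int = 2) -> PCAResult:
    """PCA of a subjects x features matrix via singular directions."""
    if isinstance(features, pd.DataFrame):
        complete = features.dropna(axis="index")
        row_index = list(complete.index)
        n_dropped = len(features) - len(complete)
        X = complete.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        keep = np.all(np.isfinite(X), axis=1)
        row_index = list(np.nonzero(keep)[0])
        n_dropped = int((~keep).sum())
        X = X[keep]
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 complete rows for PCA")
    if not 1 <= n_components <= min(X.shape):
        raise ValidationError(
            f"n_components must lie in [1, {min(X.shape)}] for shape {X.shape}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        n_components=n_components,
        row_index=row_index,
        n_dropped=n_dropped,
    )


def orient_scores(scores: np.ndarray, labels, positive_label) -> np.ndarray:
    """Flip a 1D score axis so the given class centroid is positive."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels)
    centroid = scores[labels == positive_label].mean()
    return -scores if centroid < 0 else scores.copy()


@dataclass(frozen=True)
class PCASeparationResult:
    """Label-permutation test on the centroid distance in PCA space."""

    statistic_obs: float
    p_value: float
    n_perm: int
    n_components: int
    seed: int | None
    group_sizes: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "statistic_obs": self.statistic_obs,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "n_components": self.n_components,
            "seed": self.seed,
            "group_sizes": list(self.group_sizes),
            "statistic": "pca_centroid_distance",
        }


def pca_separation_pvalue(
    features,
    labels,
    n_components: int = 2,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PCASeparationResult:
    """Permutation p-value for class separation in a fixed PCA embedding.

    The embedding is fitted once on all complete rows; the statistic is
    the Euclidean distance between class centroids in the retained
    component space; labels are then permuted, p = (1 + #>=obs)/(1 + B).
    """
    res = pca_embed(features, n_components)
    labels = np.asarray(labels)
    if isinstance(features, pd.DataFrame):
        labels = pd.Series(labels, index=features.index).loc[res.row_index].to_numpy()
    else:
        labels = labels[np.asarray(res.row_index, dtype=int)]
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 label classes, got {classes.size}")
    mask = labels == classes[0]
    n0, n1 = int(mask.sum()), int((~mask).sum())
    if min(n0, n1) < 2:
        raise ValidationError("each class needs >= 2 complete rows")

    def centroid_distance(m):
        return float(
            np.linalg.norm(res.scores[m].mean(axis=0) - res.scores[~m].mean(axis=0))
        )

    obs = centroid_distance(mask)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        perm = np.zeros(labels.size, dtype=bool)
        perm[rng.choice(labels.size, size=n0, replace=False)] = True
        if centroid_distance(perm) >= obs - 1e-12:
            extreme += 1
    p = (1.0 + extreme) / (1.0 + n_perm)
    return PCASeparationResult(obs, p, n_perm, n_components, seed, (n0, n1))


# ---------------------------------------------------------------------------
# Per-mouse courses: regression and classification
# ---------------------------------------------------------------------------

@dataclass
class MouseCourse:
    """One mouse's longitudinal record (days, PDFF mean, score, spleen)."""

    mouse_id: str
    days: np.ndarray
    mean_pdff: np.ndarray | None = None
    score: np.ndarray | None = None
    spleen_volume: np.ndarray | None = None
    group: str | None = None

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        if self.days.size < 1 or np.any(np.diff(self.days) <= 0):
            raise ValidationError("days must be non-empty and strictly increasing")
        for name in ("mean_pdff", "score", "spleen_volume"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != self.days.size:
                    raise ValidationError(f"{name} length differs from days")
                setattr(self, name, arr)


@dataclass(frozen=True)
class RegressionFit:
    """Per-mouse OLS line of the heterogeneity score over study days."""

    mouse_id: str
    slope: float
    intercept: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 2:
            raise ValidationError("a regression fit needs >= 2 points")


@dataclass(frozen=True)
class GroupLine:
    """Pooled group line: arithmetic mean of per-mouse coefficients."""

    group: str
    slope: float
    intercept: float
    n_fits: int


def fit_mouse_regression(course: MouseCourse) -> RegressionFit:
    """Exact OLS (normal equations) of score on day."""
    if course.score is None or course.days.size < 2:
        raise ValidationError("need >= 2 (day, score) points")
    if np.ptp(course.days) == 0:
        raise ValidationError("all days equal: slope undefined")
    slope, intercept = np.polyfit(course.days.astype(float), course.score, 1)
    return RegressionFit(course.mouse_id, float(slope), float(intercept), course.days.size)


def combine_group_line(fits: list[RegressionFit], group: str = "") -> GroupLine:
    if not fits:
        raise ValidationError("cannot combine an empty list of fits")
    return GroupLine(
        group=group,
        slope=float(np.mean([f.slope for f in fits])),
        intercept=float(np.mean([f.intercept for f in fits])),
        n_fits=len(fits),
    )


def summarize_violin(table: CohortTable) -> pd.DataFrame:
    """Quartiles (linear interpolation) per (group, day) violin cell."""
    rows = []
    for (group, day), sub in table.data.groupby(["group", "day"]):
        vals = sub["score"].to_numpy()
        q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
        rows.append(
            {"group": group, "day": int(day), "q1": q1, "median": med, "q3": q3, "n": len(vals)}
        )
    return pd.DataFrame(rows, columns=["group", "day", "q1", "median", "q3", "n"])


#: Spleen-volume fraction of baseline at/below which a mouse is a responder.
RESPONDER_SPLEEN_FRACTION = 0.5


def classify_mouse(course: MouseCourse) -> tuple[str, str]:
    """Disease/responder status from spleen volume and distal PDFF trend.

    responder: final spleen volume <= 50% of baseline (checked first);
    diseased: spleen volume increased from baseline AND the OLS slope of
    distal mean PDFF over days is negative; with no spleen data only the
    PDFF criterion applies (so responder is unreachable); otherwise
    indeterminate.  Returns (status, reason).
    """
    if course.mean_pdff is None or course.days.size < 2:
        return "indeterminate", "fewer than 2 time points with distal mean PDFF"
    pdff_slope = float(np.polyfit(course.days.astype(float), course.mean_pdff, 1)[0])
    spleen = course.spleen_volume
    if spleen is not None and course.days.size >= 2:
        baseline, final = float(spleen[0]), float(spleen[-1])
        if final <= RESPONDER_SPLEEN_FRACTION * baseline:
            return "responder", (
                f"spleen volume fell to {final / baseline:.0%} of baseline"
            )
        if final > baseline and pdff_slope < 0:
            return "diseased", "spleen volume increased and distal PDFF declined"
        return "indeterminate", "neither responder nor diseased criteria met"
    if pdff_slope < 0:
        return "diseased", "distal PDFF declined (no spleen data)"
    return "indeterminate", "no spleen data and no PDFF decline"
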