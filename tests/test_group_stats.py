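"""Permutation tests, PCA, regression, quartiles, classification."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import marrowvar as mv
from marrowvar.errors import ValidationError


class TestPermutationTest:
    def test_no_signal_gives_p_one(self):
        res = mv.permutation_test([5, 5, 5, 5], [5, 5, 5, 5])
        assert res.statistic_obs == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_exhaustive_enumeration_small_instance(self):
        # 20 distinct labelings of {1,2,3} vs {7,8,9}
        two = mv.permutation_test([1, 2, 3], [7, 8, 9], sides="two_sided")
        assert two.exhaustive and two.n_perm == 20
        assert two.p_value == pytest.approx(2 / 20)
        one = mv.permutation_test([1, 2, 3], [7, 8, 9], sides="one_sided_less")
        assert one.p_value == pytest.approx(1 / 20)

    def test_monte_carlo_within_three_se_of_exhaustive(self, rng):
        for _ in range(5):
            a = rng.normal(0.0, 1.0, 6)
            b = rng.normal(0.8, 1.0, 6)
            exact = mv.permutation_test(a, b, exhaustive_limit=2000)
            assert exact.exhaustive
            mc = mv.permutation_test(a, b, n_perm=10_000, seed=int(rng.integers(2**31)),
                                     exhaustive_limit=1)
            se = np.sqrt(exact.p_value * (1 - exact.p_value) / mc.n_perm)
            assert abs(mc.p_value - exact.p_value) <= 3 * se + 2 / mc.n_perm

    def test_agrees_with_scipy_exact(self, rng):
        a = rng.uniform(0, 100, 5)
        b = rng.uniform(20, 120, 6)
        ours = mv.permutation_test(a, b, sides="two_sided", exhaustive_limit=10**6)

        def diff_means(x, y, axis):
            return np.mean(x, axis=axis) - np.mean(y, axis=axis)

        ref = scipy.stats.permutation_test(
            (a, b), diff_means, permutation_type="independent",
            alternative="two-sided", n_resamples=np.inf,
        )
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_seed_reproducibility(self):
        a, b = np.arange(30.0), np.arange(30.0) + 0.5
        r1 = mv.permutation_test(a, b, n_perm=500, seed=42)
        r2 = mv.permutation_test(a, b, n_perm=500, seed=42)
        assert r1.p_value == r2.p_value

    def test_type_one_error_calibrated(self, rng):
        """Null rejection rate at alpha=0.05 over 1000 simulated datasets."""
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            x = rng.normal(0.0, 1.0, 20)
            res = mv.permutation_test(
                x[:10], x[10:], sides="two_sided", n_perm=499,
                seed=int(rng.integers(2**31)), exhaustive_limit=1,
            )
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            mv.permutation_test([1.0], [2.0, 3.0])


class TestPCA:
    def test_collinear_points_one_component(self):
        res = mv.pca_embed(np.array([[-1.0, 0.0], [1.0, 0.0]]), n_components=1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        X = np.array([[1.0, 2.0], [3.0, 3.0], [5.0, 7.0]])
        res = mv.pca_embed(X, n_components=2)
        C = np.cov((X - X.mean(axis=0)).T)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in range(2):
            v = evecs[:, k]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.allclose(res.loadings[k], v, atol=1e-9)
        frac = evals / evals.sum()
        assert np.allclose(res.explained_variance_ratio, frac, atol=1e-9)

    def test_scores_centered_and_reconstruction(self, rng):
        X = rng.normal(size=(10, 4))
        res = mv.pca_embed(X, n_components=4)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)
        recon = res.scores @ res.loadings + X.mean(axis=0)
        assert np.allclose(recon, X, atol=1e-9)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_missing_rows_dropped_not_imputed(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0, 4.0], "b": [0.0, 1.0, 2.0, 1.0]})
        res = mv.pca_embed(df, n_components=1)
        assert res.n_dropped == 1
        assert len(res.row_index) == 3

    def test_fixture_day0_healthy_scores_all_negative(self, table1):
        """1D baseline PCA: healthy mice cluster on the negative axis when
        the disease centroid is oriented positive."""
        day0 = table1.data[table1.data["day"] == 0]
        healthy = day0.loc[day0["group"] == "healthy", "score"].to_numpy()
        disease = day0.loc[day0["group"] != "healthy", "score"].to_numpy()
        values = np.concatenate([healthy, disease])[:, None]
        labels = np.array(["healthy"] * len(healthy) + ["disease"] * len(disease))
        res = mv.pca_embed(values, n_components=1)
        scores = mv.orient_scores(res.scores[:, 0], labels, "disease")
        assert np.all(scores[labels == "healthy"] < 0)


class TestPCASeparation:
    def test_distinct_clusters_minimal_p(self, rng):
        # groups of 10 so a random relabelling essentially never reproduces
        # the observed split; every permuted distance is then strictly smaller
        X = np.vstack([rng.normal(0.0, 0.1, (10, 2)), rng.normal(50.0, 0.1, (10, 2))])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        res = mv.pca_separation_pvalue(X, labels, n_components=2, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_null_labels_give_large_p(self, rng):
        X = rng.normal(0.0, 1.0, (16, 2))
        ps = []
        for seed in range(21):
            labels = rng.permutation(np.array(["a"] * 8 + ["b"] * 8))
            ps.append(
                mv.pca_separation_pvalue(X, labels, n_perm=199, seed=seed).p_value
            )
        assert np.median(ps) > 0.3

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValidationError):
            mv.pca_separation_pvalue(X, np.array(["a"] * 6), n_perm=10)

    def test_fixture_day0_separation_significant(self, table1):
        day0 = table1.data[table1.data["day"] == 0]
        values = day0["score"].to_numpy()[:, None]
        labels = np.where(day0["group"] == "healthy", "healthy", "disease")
        res = mv.pca_separation_pvalue(values, labels, n_components=1,
                                       n_perm=2000, seed=3)
        assert res.p_value < 0.05


class TestRegression:
    def test_exact_line_recovered(self):
        course = mv.MouseCourse("m", days=[0, 1, 2], score=[10.0, 8.0, 6.0])
        fit = mv.fit_mouse_regression(course)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.intercept == pytest.approx(10.0)

    def test_normal_equations_hand_value(self):
        course = mv.MouseCourse("m", days=[0, 1, 2], score=[1.0, 3.0, 4.0])
        fit = mv.fit_mouse_regression(course)
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(7.0 / 6.0)

    def test_slope_recovery_under_noise(self, rng):
        """Mean estimated slope within 2 SE of truth on noisy linear courses."""
        true_slope = -1.5
        days = np.array([0, 20, 40, 60])
        slopes = []
        for _ in range(200):
            y = 100.0 + true_slope * days + rng.normal(0.0, 5.0, days.size)
            slopes.append(
                mv.fit_mouse_regression(mv.MouseCourse("m", days=days, score=y)).slope
            )
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - true_slope) <= 2 * se

    def test_fixture_disease1_slopes_all_negative(self, table1):
        wide = table1.to_wide("disease1")
        for mouse, row in wide.iterrows():
            present = row.dropna()
            if len(present) < 2:
                continue
            fit = mv.fit_mouse_regression(
                mv.MouseCourse(str(mouse), days=present.index.to_numpy(),
                               score=present.to_numpy())
            )
            assert fit.slope < 0

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            mv.fit_mouse_regression(mv.MouseCourse("m", days=[0], score=[1.0]))

    def test_group_line_is_mean_of_fits(self):
        f1 = mv.RegressionFit("a", -2.0, 10.0, 3)
        f2 = mv.RegressionFit("b", -4.0, 20.0, 3)
        line = mv.combine_group_line([f1, f2], group="g")
        assert (line.slope, line.intercept) == (-3.0, 15.0)
        single = mv.combine_group_line([f1], group="g")
        assert (single.slope, single.intercept) == (f1.slope, f1.intercept)

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ValidationError):
            mv.combine_group_line([])


class TestViolinSummary:
    def test_single_value_degenerate_quartiles(self):
        t = mv.CohortTable(pd.DataFrame(
            {"group": ["g"], "mouse_id": [1], "day": [0], "score": [7.0]}
        ))
        row = mv.summarize_violin(t).iloc[0]
        assert row["q1"] == row["median"] == row["q3"] == 7.0
        assert row["n"] == 1

    def test_healthy_fixture_quartiles(self, table1):
        q = mv.summarize_violin(table1)
        row = q[(q["group"] == "healthy") & (q["day"] == 0)].iloc[0]
        assert row["median"] == pytest.approx(46.58)
        assert row["q1"] == pytest.approx(25.96, abs=0.005)
        assert row["q3"] == pytest.approx(71.37, abs=0.005)
        assert row["n"] == 15

    def test_one_row_per_group_day_cell(self, table1):
        q = mv.summarize_violin(table1)
        cells = table1.data.groupby(["group", "day"]).ngroups
        assert len(q) == cells


class TestClassification:
    def test_spleen_halving_makes_responder(self):
        course = mv.MouseCourse(
            "m", days=[0, 30], mean_pdff=[10.0, 30.0], spleen_volume=[100.0, 45.0]
        )
        assert mv.classify_mouse(course)[0] == "responder"

    def test_flat_everything_indeterminate(self):
        course = mv.MouseCourse(
            "m", days=[0, 30], mean_pdff=[40.0, 40.0], spleen_volume=[100.0, 100.0]
        )
        assert mv.classify_mouse(course)[0] == "indeterminate"

    def test_growing_spleen_falling_pdff_is_diseased(self):
        course = mv.MouseCourse(
            "m", days=[0, 30], mean_pdff=[40.0, 10.0], spleen_volume=[100.0, 130.0]
        )
        assert mv.classify_mouse(course)[0] == "diseased"

    def test_responder_check_precedes_diseased(self):
        # falling PDFF but halved spleen: responder wins
        course = mv.MouseCourse(
            "m", days=[0, 30], mean_pdff=[40.0, 30.0], spleen_volume=[100.0, 40.0]
        )
        assert mv.classify_mouse(course)[0] == "responder"

    def test_no_spleen_data_cannot_be_responder(self):
        falling = mv.MouseCourse("m", days=[0, 30], mean_pdff=[40.0, 10.0])
        rising = mv.MouseCourse("m", days=[0, 30], mean_pdff=[10.0, 40.0])
        assert mv.classify_mouse(falling)[0] == "diseased"
        assert mv.classify_mouse(rising)[0] == "indeterminate"

    def test_single_time_point_indeterminate_with_reason(self):
        course = mv.MouseCourse("m", days=[0], mean_pdff=[40.0])
        status, reason = mv.classify_mouse(course)
        assert status == "indeterminate"
        assert "time point" in reason
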