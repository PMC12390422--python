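"""Trimmed-variance scoring: oracle agreement, invariances, bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import marrowvar as mv
from marrowvar.errors import DegenerateROIError, ValidationError
from marrowvar.heterogeneity import HeterogeneityParams, trim_values

value_lists = st.lists(
    st.floats(min_value=0.0, max_value=100.0, allow_nan=False), min_size=2, max_size=60
)


def oracle_trimmed_variance(values, pct=90.0, ddof=1):
    """Brute force: sort, interpolate the percentile, filter, two-pass variance."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    pos = (pct / 100.0) * (n - 1)
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    thr = x[lo] + (pos - lo) * (x[hi] - x[lo])
    kept = [v for v in values if v <= thr]
    m = sum(kept) / len(kept)
    return sum((v - m) ** 2 for v in kept) / (len(kept) - ddof)


class TestRoiValues:
    def test_constant_volume_returns_constant_per_voxel(self):
        values = np.full((2, 3, 2), 50.0)
        mask = np.zeros((2, 3, 2), dtype=bool)
        mask[0] = True
        out = mv.roi_values(mv.PDFFVolume(values), mv.ROIMask(mask))
        assert out.tolist() == [50.0] * 6

    def test_length_matches_mask_count(self, healthy_phantom):
        vol, mask = healthy_phantom
        assert mv.roi_values(vol, mask).size == mask.n_voxels

    def test_only_in_mask_voxels_sampled(self, healthy_phantom):
        vol, mask = healthy_phantom
        distal = mask.region("distal")
        vals = mv.roi_values(vol, distal)
        # background is NaN sentinel; a leak would surface as NaN here
        assert np.isfinite(vals).all()
        assert vals.size == distal.n_voxels

    def test_nonfinite_in_mask_value_rejected(self):
        values = np.full((2, 2, 2), 50.0)
        values[0, 0, 0] = np.nan
        mask = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ValidationError, match="non-finite"):
            mv.roi_values(mv.PDFFVolume(values), mv.ROIMask(mask))


class TestTrimmedVariance:
    def test_equal_values_score_zero(self):
        assert mv.trimmed_variance([7.0] * 10) == 0.0

    def test_one_to_ten_trimmed_at_90(self):
        # threshold 9.1, retained 1..9, sample variance 7.5
        vals = np.arange(1.0, 11.0)
        retained, thr = trim_values(vals, 90.0)
        assert thr == pytest.approx(9.1)
        assert retained.tolist() == list(range(1, 10))
        assert mv.trimmed_variance(vals) == pytest.approx(7.5)

    def test_trim_100_keeps_everything(self):
        params = HeterogeneityParams(trim_percentile=100.0)
        assert mv.trimmed_variance([2.0, 4.0, 6.0], params) == pytest.approx(4.0)

    def test_population_convention(self):
        params = HeterogeneityParams(trim_percentile=100.0, variance_convention="population")
        assert mv.trimmed_variance([2.0, 4.0, 6.0], params) == pytest.approx(8.0 / 3.0)

    def test_matches_bruteforce_oracle_on_random_lists(self, rng):
        for _ in range(1000):
            n = rng.integers(2, 201)
            vals = rng.uniform(0.0, 100.0, n)
            if n == 2:  # a 90% trim of two values always retains just one
                with pytest.raises(DegenerateROIError):
                    mv.trimmed_variance(vals)
                continue
            got = mv.trimmed_variance(vals)
            want = oracle_trimmed_variance(vals)
            assert got == pytest.approx(want, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(values=value_lists, seed=st.integers(0, 2**16))
    def test_permutation_invariance(self, values, seed):
        vals = np.asarray(values)
        shuffled = np.random.default_rng(seed).permutation(vals)
        try:
            a = mv.trimmed_variance(vals)
        except DegenerateROIError:
            with pytest.raises(DegenerateROIError):
                mv.trimmed_variance(shuffled)
            return
        assert mv.trimmed_variance(shuffled) == pytest.approx(a, rel=1e-12, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(values=value_lists)
    def test_trimming_removes_extreme_outlier_inflation(self, values):
        """Appending a far outlier inflates the untrimmed variance but not
        the trimmed score; with no value above the threshold (trim 100)
        the score equals the plain variance exactly."""
        vals = np.asarray(values)
        outlier = vals.max() + 100.0 * (np.ptp(vals) + 1.0)
        augmented = np.append(vals, outlier)
        try:
            trimmed = mv.trimmed_variance(augmented)
        except DegenerateROIError:
            return
        full = mv.trimmed_variance(augmented, HeterogeneityParams(trim_percentile=100.0))
        assert trimmed < full
        assert mv.trimmed_variance(
            vals, HeterogeneityParams(trim_percentile=100.0)
        ) == pytest.approx(np.var(vals, ddof=1))

    def test_degenerate_roi_carries_counts(self):
        with pytest.raises(DegenerateROIError) as err:
            mv.trimmed_variance([1.0])
        assert err.value.n_total == 1


class TestScoreDataset:
    def test_singleton_dataset_gives_one_record(self, small_geom):
        ds = mv.simulate_study([(mv.healthy_course(), 1)], geom=small_geom, seed=4)
        table = mv.score_dataset(ds)
        assert len(table) == 1
        rec = table.data.iloc[0]
        assert rec["n_voxels_retained"] <= rec["n_voxels_total"]
        assert rec["trim_percentile"] == 90.0

    def test_one_record_per_manifest_row(self, small_geom):
        specs = mv.default_study_specs(n_healthy=2, n_disease1=3, n_disease2=2,
                                       dropout_prob=0.0)
        ds = mv.simulate_study(specs, geom=small_geom, seed=4)
        table = mv.score_dataset(ds)
        assert len(table) == len(ds)

    def test_wide_layout_mirrors_study_schedule(self, small_geom):
        specs = [(mv.nonresponder_course((0, 64, 69, 74), dropout_prob=0.0,
                                         label="disease1"), 3)]
        ds = mv.simulate_study(specs, geom=small_geom, seed=4)
        wide = mv.score_dataset(ds).to_wide("disease1")
        assert list(wide.columns) == [0, 64, 69, 74]
        assert len(wide) == 3

    def test_healthy_scores_near_calibrated_target(self, small_geom):
        """Mean healthy score tracks the trim-adjusted generating variance."""
        ds = mv.simulate_study([(mv.healthy_course(), 50)], geom=small_geom, seed=8)
        table = mv.score_dataset(ds)
        rng = np.random.default_rng(0)
        from marrowvar.phantom import HEALTHY_DISTAL_VARIANCE, _draw_pdff

        draws = _draw_pdff(rng, 50.0, HEALTHY_DISTAL_VARIANCE, 1_000_000)
        thr = np.percentile(draws, 90.0)
        oracle = draws[draws <= thr].var(ddof=1)
        assert table.data["score"].mean() == pytest.approx(oracle, rel=0.15)


class TestHeatmapSlice:
    def test_scale_pinned_regardless_of_data(self, healthy_phantom):
        vol, mask = healthy_phantom
        hm = mv.heatmap_slice(vol, mask, vol.shape[vol.bone_axis] - 1)
        assert (hm.vmin, hm.vmax) == (0.0, 100.0)

    def test_out_of_mask_is_sentinel_not_zero(self, healthy_phantom):
        vol, mask = healthy_phantom
        s = vol.shape[vol.bone_axis] - 1
        hm = mv.heatmap_slice(vol, mask, s)
        memb = np.moveaxis(mask.membership, mask.bone_axis, 0)[s]
        assert np.isnan(hm.values[~memb]).all()

    def test_in_mask_values_identity(self, healthy_phantom):
        vol, mask = healthy_phantom
        s = vol.shape[vol.bone_axis] - 1
        hm = mv.heatmap_slice(vol, mask, s)
        vals = np.moveaxis(vol.values, vol.bone_axis, 0)[s]
        memb = np.moveaxis(mask.membership, mask.bone_axis, 0)[s]
        assert np.array_equal(hm.values[memb], vals[memb])

    def test_slice_without_mask_rejected(self, healthy_phantom):
        vol, mask = healthy_phantom
        trimmed = mask.membership.copy()
        idx = [slice(None)] * 3
        idx[mask.bone_axis] = 0
        trimmed[tuple(idx)] = False
        with pytest.raises(ValidationError, match="no mask voxels"):
            mv.heatmap_slice(vol, mv.ROIMask(trimmed, bone_axis=mask.bone_axis), 0)
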