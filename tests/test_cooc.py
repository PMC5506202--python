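import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import label as cc_label

import linecooc as lc
from linecooc.cooc import InterestPointSet, kernel_l2
from linecooc.oscore import OrientationMap

from conftest import brute_force_histogram


def _points(x, y, k, n_theta=16, theta=None):
    return InterestPointSet(
        x=np.asarray(x), y=np.asarray(y), k=np.asarray(k), n_theta=n_theta,
        theta=None if theta is None else np.asarray(theta),
    )


class TestThinning:
    def test_empty_and_already_thin(self):
        empty = np.zeros((10, 10), dtype=np.uint8)
        assert lc.thin_to_centerlines(empty).sum() == 0
        line = np.zeros((10, 10), dtype=np.uint8)
        line[5, 1:9] = 1
        assert np.array_equal(lc.thin_to_centerlines(line), line)

    def test_wide_bar_thins_to_connected_path(self):
        bar = np.zeros((20, 30), dtype=np.uint8)
        bar[8:13, 2:28] = 1
        thin = lc.thin_to_centerlines(bar)
        # 1-px wide: no 2x2 block fully set
        blocks = thin[:-1, :-1] + thin[1:, :-1] + thin[:-1, 1:] + thin[1:, 1:]
        assert blocks.max() <= 3
        _, n = cc_label(thin, structure=np.ones((3, 3)))
        assert n == 1

    def test_non_binary_raises(self):
        with pytest.raises(ValueError):
            lc.thin_to_centerlines(np.arange(9).reshape(3, 3))


class TestInterestPoints:
    def test_one_point_per_centerline_pixel(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 1:4] = 1
        omap = OrientationMap(
            angle_index=np.full((5, 5), 3), defined_mask=np.ones((5, 5), bool),
            theta_bins=np.zeros(16),
        )
        pts = lc.build_interest_points(mask, omap)
        assert len(pts) == 3
        assert np.all(pts.k == 3)
        empty = lc.build_interest_points(np.zeros((5, 5), np.uint8), omap)
        assert len(empty) == 0

    def test_undefined_orientation_raises_with_pixel(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        omap = OrientationMap(
            angle_index=np.full((5, 5), -1), defined_mask=np.zeros((5, 5), bool),
            theta_bins=np.zeros(16),
        )
        with pytest.raises(ValueError, match=r"x=2, y=2"):
            lc.build_interest_points(mask, omap)


class TestShiftTwistDifferences:
    def test_collinear_pair_symmetrized(self):
        pts = _points([0, 5], [0, 0], [8, 8])  # bin 8 = angle 0 for n=16
        diffs = lc.shift_twist_differences(pts, d=65)
        kern = lc.accumulate_kernel(diffs)
        d = 65
        assert kern.values[d + 5, d, 0] == pytest.approx(1.0)
        assert kern.values[d - 5, d, 0] == pytest.approx(1.0)
        assert kern.values.sum() == pytest.approx(2.0)  # 2 ordered pairs

    def test_distance_cut(self):
        pts = _points([0, 70], [0, 0], [8, 8])
        assert len(lc.shift_twist_differences(pts, d=65)) == 0

    def test_invalid_d(self):
        with pytest.raises(ValueError):
            lc.shift_twist_differences(_points([0], [0], [0]), d=0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n = 200
        pts = _points(
            rng.integers(0, 40, n), rng.integers(0, 40, n), rng.integers(0, 16, n)
        )
        kern = lc.accumulate_kernel(lc.shift_twist_differences(pts, d=12), 12, 16)
        oracle = brute_force_histogram(pts, 12, 16)
        assert np.array_equal(kern.values, oracle)

    def test_shift_twist_invariance(self):
        """Translating the point set, or rotating positions and orientations
        by one bin, leaves >= 99% of the normalized kernel mass in identical
        bins. Points are confined to a disk of radius d/2 so every pair
        passes the window cut in both frames."""
        rng = np.random.default_rng(3)
        n = 300
        r = 10 * np.sqrt(rng.random(n))
        phi = rng.uniform(0, 2 * np.pi, n)
        x = np.rint(r * np.cos(phi))
        y = np.rint(r * np.sin(phi))
        k = rng.integers(0, 16, n)
        d = 20

        def kern(px, py, pk):
            pts = _points(px, py, pk)
            return lc.normalize_kernel(
                lc.accumulate_kernel(lc.shift_twist_differences(pts, d), d, 16)
            )

        base = kern(x, y, k)
        shifted = kern(x + 40, y - 17, k)
        assert np.array_equal(base.values, shifted.values)

        step = np.pi / 16
        c, s = np.cos(step), np.sin(step)
        rot = kern(c * x - s * y, s * x + c * y, (k + 1) % 16)
        common = np.minimum(base.values, rot.values).sum()
        assert common >= 0.99


class TestKernelOps:
    def test_accumulate_trivial_cases(self):
        from linecooc.cooc import ShiftTwistDifferenceSet

        empty = ShiftTwistDifferenceSet(
            dx=np.empty(0, int), dy=np.empty(0, int), dk=np.empty(0, int),
            weight=np.empty(0), d=3, n_theta=4,
        )
        assert lc.accumulate_kernel(empty).values.sum() == 0
        one = ShiftTwistDifferenceSet(
            dx=np.array([2]), dy=np.array([0]), dk=np.array([0]),
            weight=np.array([1.0]), d=3, n_theta=4,
        )
        kern = lc.accumulate_kernel(one)
        assert kern.values[5, 3, 0] == 1.0
        assert np.count_nonzero(kern.values) == 1

    def test_accumulate_out_of_bounds_raises(self):
        from linecooc.cooc import ShiftTwistDifferenceSet

        bad = ShiftTwistDifferenceSet(
            dx=np.array([9]), dy=np.array([0]), dk=np.array([0]),
            weight=np.array([1.0]), d=3, n_theta=4,
        )
        with pytest.raises(ValueError):
            lc.accumulate_kernel(bad)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_normalize_kernel_simplex_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((5, 5, 3))
        kern = lc.CooccurrenceKernel(vals, d=2, n_theta=3)
        normed = lc.normalize_kernel(kern)
        assert normed.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert normed.values.min() >= 0
        again = lc.normalize_kernel(normed)
        assert np.allclose(again.values, normed.values)

    def test_normalize_zero_mass_raises(self):
        kern = lc.CooccurrenceKernel(np.zeros((3, 3, 2)), d=1, n_theta=2)
        with pytest.raises(ValueError):
            lc.normalize_kernel(kern)

    def test_uniform_kernel_normalizes_to_uniform(self):
        kern = lc.CooccurrenceKernel(np.ones((3, 3, 2)), d=1, n_theta=2)
        assert np.allclose(lc.normalize_kernel(kern).values, 1 / 18)

    def test_inversion_symmetry(self):
        """Accumulated kernels are symmetric under spatial point reflection
        (antipodal accumulation of unpolarized lines)."""
        rng = np.random.default_rng(11)
        n = 100
        pts = _points(
            rng.integers(0, 30, n), rng.integers(0, 30, n), rng.integers(0, 16, n)
        )
        kern = lc.accumulate_kernel(lc.shift_twist_differences(pts, 10), 10, 16)
        assert np.array_equal(kern.values, kern.values[::-1, ::-1, :])


class TestAVKernels:
    def test_combination_rules(self):
        rng = np.random.default_rng(2)
        a = lc.CooccurrenceKernel(rng.random((5, 5, 4)), d=2, n_theta=4)
        zero = lc.CooccurrenceKernel(np.zeros((5, 5, 4)), d=2, n_theta=4)
        assert np.array_equal(lc.combine_av_kernels(a, zero).values, a.values)
        both = lc.combine_av_kernels(a, a)
        assert np.array_equal(both.values, 2 * a.values)

    def test_combined_equals_whole_minus_cross_label_pairs(self):
        """Two disjoint labeled curves: AV-separated kernel = whole-set
        kernel minus exactly the cross-label contributions."""
        rng = np.random.default_rng(5)
        xa = rng.integers(0, 15, 60)
        ya = rng.integers(0, 15, 60)
        xb = rng.integers(0, 15, 60)
        yb = rng.integers(20, 35, 60)
        ka = rng.integers(0, 16, 60)
        kb = rng.integers(0, 16, 60)
        pa = _points(xa, ya, ka)
        pb = _points(xb, yb, kb)
        pall = _points(
            np.concatenate([xa, xb]), np.concatenate([ya, yb]), np.concatenate([ka, kb])
        )
        d = 30
        ha = brute_force_histogram(pa, d, 16)
        hb = brute_force_histogram(pb, d, 16)
        hall = brute_force_histogram(pall, d, 16)
        combined = lc.combine_av_kernels(
            lc.accumulate_kernel(lc.shift_twist_differences(pa, d), d, 16),
            lc.accumulate_kernel(lc.shift_twist_differences(pb, d), d, 16),
        )
        assert np.allclose(combined.values, ha + hb)
        cross = hall - ha - hb
        assert cross.sum() > 0  # there really are cross-label pairs in range
        assert np.allclose(hall - combined.values, cross)


class TestKernelDistance:
    def test_zero_for_identical(self):
        rng = np.random.default_rng(0)
        k = lc.normalize_kernel(lc.CooccurrenceKernel(rng.random((5, 5, 4)), 2, 4))
        assert lc.kernel_distance(k, k) == 0.0

    def test_one_hot_closed_form(self):
        a = np.zeros((3, 3, 2))
        b = np.zeros((3, 3, 2))
        a[0, 0, 0] = 1.0
        b[2, 2, 1] = 1.0
        assert lc.kernel_distance(a, b) == pytest.approx(100 * np.sqrt(2))
        assert kernel_l2(a, b) == pytest.approx(np.sqrt(2))

    def test_symmetric_variant_and_shape_check(self):
        a = np.zeros((3, 3, 2))
        a[0, 0, 0] = 1.0
        b = 0.5 * a
        assert lc.kernel_distance(a, b, symmetric=True) == pytest.approx(50.0)
        with pytest.raises(ValueError):
            lc.kernel_distance(a, np.zeros((5, 5, 2)))


class TestLineCooccurrenceEstimator:
    def test_fit_accumulates_and_normalizes(self):
        pts1 = _points([0, 5], [0, 0], [8, 8])
        pts2 = _points([0, 0], [0, 7], [4, 4])
        est = lc.LineCooccurrence(d=10, n_theta=16).fit([pts1, pts2])
        assert est.kernel_.normalized
        assert est.kernel_.values.sum() == pytest.approx(1.0)
        assert est.counts_.values.sum() == pytest.approx(4.0)
        assert est.n_samples_ == 2
        params = est.get_params()
        assert params == {"d": 10, "n_theta": 16}
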