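"""Segmentation loss/metric identities and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from metseg import metrics


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        g = np.zeros((8, 8, 8))
        g[2:5, 2:5, 2:5] = 1
        assert metrics.dice_loss(g, g) == pytest.approx(0.0)

    def test_disjoint_masks_is_one(self):
        g = np.zeros((8, 8, 8))
        p = np.zeros((8, 8, 8))
        g[:2], p[6:] = 1, 1
        assert metrics.dice_loss(g, p) == pytest.approx(1.0)

    def test_hand_computed_third(self):
        # G has 2 voxels; P = 0.5 on 4 voxels including both of G:
        # L = 1 - 2*(2*0.5) / (2 + 4*0.25) = 1 - 2/3 = 1/3
        g = np.zeros(8)
        g[:2] = 1
        p = np.zeros(8)
        p[:4] = 0.5
        assert metrics.dice_loss(g, p) == pytest.approx(1 / 3)

    def test_both_empty_smoothed(self):
        # both sums zero: the epsilon enters the denominator, loss = 1 - 0/eps
        z = np.zeros((4, 4, 4))
        assert metrics.dice_loss(z, z) == pytest.approx(1.0)

    def test_monotone_in_probability(self):
        g = np.zeros((6, 6, 6))
        g[2:4, 2:4, 2:4] = 1
        losses = [metrics.dice_loss(g, g * p) for p in (0.2, 0.5, 0.8, 1.0)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            metrics.dice_loss(np.zeros(3), np.zeros(4))


class TestDsc:
    def test_identities(self):
        a = np.zeros((8, 8, 8), bool)
        a[2:6, 2:6, 2:6] = True
        assert metrics.dsc(a, a) == pytest.approx(100.0)
        assert metrics.dsc(a, ~a) == pytest.approx(0.0)
        assert metrics.dsc(np.zeros_like(a), np.zeros_like(a)) == pytest.approx(100.0)

    def test_partial_overlap(self):
        a = np.zeros(300, bool)
        b = np.zeros(300, bool)
        a[:100] = True
        b[20:120] = True  # overlap 80
        assert metrics.dsc(a, b) == pytest.approx(80.0)

    def test_symmetry(self, rng):
        a = rng.random((10, 10, 10)) > 0.7
        b = rng.random((10, 10, 10)) > 0.7
        assert metrics.dsc(a, b) == pytest.approx(metrics.dsc(b, a))


def brute_hausdorff(a, b, spacing):
    """All-pairs surface-voxel oracle."""
    pa = metrics.surface_voxels(a) * np.asarray(spacing)
    pb = metrics.surface_voxels(b) * np.asarray(spacing)
    d = cdist(pa, pb)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestHausdorff:
    def test_identical_zero(self, ball):
        a = ball((16, 16, 16), (8, 8, 8), 4)
        assert metrics.hausdorff(a, a) == pytest.approx(0.0)

    def test_two_points(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[2, 5, 5] = True
        b[5, 5, 5] = True
        assert metrics.hausdorff(a, b) == pytest.approx(3.0)

    def test_nested_cubes_vs_brute_force(self):
        a = np.zeros((14, 14, 14), bool)
        b = np.zeros((14, 14, 14), bool)
        a[2:12, 2:12, 2:12] = True
        b[5:9, 5:9, 5:9] = True
        assert metrics.hausdorff(a, b) == pytest.approx(brute_hausdorff(a, b, (1, 1, 1)))

    def test_random_masks_vs_brute_force(self, rng, ball):
        for _ in range(5):
            c1 = rng.integers(5, 11, 3)
            c2 = rng.integers(5, 11, 3)
            a = ball((16, 16, 16), c1, rng.uniform(2, 4))
            b = ball((16, 16, 16), c2, rng.uniform(2, 4))
            spacing = rng.uniform(0.5, 2.0, 3)
            assert metrics.hausdorff(a, b, spacing) == pytest.approx(
                brute_hausdorff(a, b, spacing)
            )
            assert metrics.hausdorff(a, b, spacing) == pytest.approx(
                metrics.hausdorff(b, a, spacing)
            )

    def test_empty_mask_raises(self):
        a = np.zeros((4, 4, 4), bool)
        b = a.copy()
        b[1, 1, 1] = True
        with pytest.raises(ValueError):
            metrics.hausdorff(a, b)


class TestVee:
    def test_identical_zero(self, ball):
        a = ball((12, 12, 12), (6, 6, 6), 3)
        assert metrics.vee(a, a) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "spacing,expected",
        [((1.0, 1.0, 1.0), 0.1), ((2.0, 2.0, 2.0), 0.8)],
    )
    def test_hundred_voxel_difference(self, spacing, expected):
        a = np.zeros(2000, bool)
        b = np.zeros(2000, bool)
        a[:1000] = True
        b[:900] = True
        a = a.reshape(10, 10, 20)
        b = b.reshape(10, 10, 20)
        assert metrics.vee(a, b, spacing) == pytest.approx(expected)


def brute_ld(mask, spacing):
    """All-pairs in-slice oracle for the in-plane longest diameter."""
    idx = np.argwhere(mask).astype(float)
    if len(idx) == 0:
        return 0.0
    best = 0.0
    spacing = np.asarray(spacing)
    for ax in range(3):
        others = [a for a in range(3) if a != ax]
        for s in np.unique(idx[:, ax]):
            pts = idx[idx[:, ax] == s][:, others] * spacing[others]
            if len(pts) > 1:
                best = max(best, cdist(pts, pts).max())
    return best


class TestLongestDiameter:
    def test_empty_is_zero(self):
        assert metrics.longest_diameter(np.zeros((5, 5, 5), bool)) == 0.0

    def test_single_voxel_is_zero(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert metrics.longest_diameter(m) == 0.0

    def test_two_voxels_in_axial_slice(self):
        m = np.zeros((10, 10, 10), bool)
        m[5, 1, 5] = True
        m[5, 8, 5] = True
        assert metrics.longest_diameter(m) == pytest.approx(7.0)

    def test_digital_sphere_vs_brute_force(self, ball):
        m = ball((16, 16, 16), (8, 8, 8), 5)
        ld = metrics.longest_diameter(m)
        assert ld == pytest.approx(brute_ld(m, (1, 1, 1)))
        assert 9.0 <= ld <= 10.5  # ~10 mm band for a radius-5 digital sphere

    def test_matches_brute_force_on_random_blobs(self, rng, ball):
        for _ in range(5):
            m = ball((14, 14, 14), rng.integers(4, 10, 3), rng.uniform(2, 4.5))
            spacing = rng.uniform(0.5, 2.0, 3)
            assert metrics.longest_diameter(m, spacing) == pytest.approx(
                brute_ld(m, spacing)
            )

    def test_translation_invariance(self, ball):
        m = ball((20, 20, 20), (7, 7, 7), 4)
        shifted = np.roll(m, (3, 2, 1), axis=(0, 1, 2))
        assert metrics.longest_diameter(m) == pytest.approx(
            metrics.longest_diameter(shifted)
        )


class TestSizeCategory:
    @pytest.mark.parametrize(
        "ld,cat", [(5, "small"), (10, "small"), (10.1, "medium"), (20, "medium"), (20.1, "large")]
    )
    def test_strata(self, ld, cat):
        assert metrics.size_category(ld) == cat
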