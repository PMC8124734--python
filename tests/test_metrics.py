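"""Overlap and surface-distance metrics vs brute-force oracles."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mscdunet as M
from mscdunet.metrics import EmptyStructureError


def surface_oracle(mask, spacing):
    """Foreground voxels with any 6-neighbor outside (grid edge = outside)."""
    pts = []
    d, h, w = mask.shape
    for i, j, k in product(range(d), range(h), range(w)):
        if not mask[i, j, k]:
            continue
        on_surface = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ii, jj, kk = i + di, j + dj, k + dk
            if not (0 <= ii < d and 0 <= jj < h and 0 <= kk < w) or not mask[ii, jj, kk]:
                on_surface = True
                break
        if on_surface:
            pts.append((i * spacing[0], j * spacing[1], k * spacing[2]))
    return np.array(pts)


def all_pairs_metrics(g, p, spacing):
    """O(n^2) hd95 / asd via explicit point-set distances."""
    gs = surface_oracle(g, spacing)
    ps = surface_oracle(p, spacing)
    dmat = np.sqrt(((gs[:, None, :] - ps[None, :, :]) ** 2).sum(-1))
    d_gp = dmat.min(axis=1)
    d_pg = dmat.min(axis=0)
    hd = max(np.percentile(d_gp, 95), np.percentile(d_pg, 95))
    a = 0.5 * (d_gp.mean() + d_pg.mean())
    return hd, a


def random_mask(rng, shape, p=0.3):
    while True:
        m = rng.random(shape) < p
        if m.any():
            return m


class TestDice:
    def test_identical_masks(self, rng):
        m = random_mask(rng, (5, 5, 5))
        assert M.dice(m, m) == 100.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert M.dice(a, b) == 0.0

    def test_shifted_block_is_fifty_percent(self):
        g = np.zeros((4, 4, 4), bool)
        p = np.zeros((4, 4, 4), bool)
        g[0:2, 0:2, 0:2] = True
        p[1:3, 0:2, 0:2] = True
        assert M.dice(g, p) == pytest.approx(50.0)

    def test_both_empty_is_perfect_agreement(self):
        z = np.zeros((3, 3, 3), bool)
        assert M.dice(z, z) == 100.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            M.dice(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))


class TestSurfaceVoxels:
    def test_single_voxel(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        pts = M.surface_voxels(m)
        assert pts.shape == (1, 3)
        assert tuple(pts[0]) == (1, 1, 1)

    def test_solid_cube_shell(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        pts = M.surface_voxels(m)
        assert len(pts) == 26  # 27 minus the fully interior center

    def test_full_grid_boundary_layer(self):
        m = np.ones((4, 4, 4), bool)
        pts = M.surface_voxels(m)
        # all voxels except the 2x2x2 interior
        assert len(pts) == 64 - 8

    def test_matches_loop_oracle(self, rng):
        m = random_mask(rng, (6, 6, 6))
        got = M.surface_voxels(m, (1.0, 2.0, 0.5))
        expect = surface_oracle(m, (1.0, 2.0, 0.5))
        assert set(map(tuple, got)) == set(map(tuple, expect))

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyStructureError):
            M.surface_voxels(np.zeros((3, 3, 3), bool))


class TestDistances:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng, (5, 5, 5))
        assert M.hd95(m, m) == 0.0
        assert M.asd(m, m) == 0.0

    def test_two_single_voxels(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        assert M.hd95(a, b) == pytest.approx(3.0)
        assert M.asd(a, b) == pytest.approx(3.0)

    def test_matches_all_pairs_oracle(self, rng):
        for trial in range(25):
            shape = tuple(rng.integers(4, 9) for _ in range(3))
            g = random_mask(rng, shape)
            p = random_mask(rng, shape)
            spacing = (1.0, 1.0, 1.0)
            hd_o, asd_o = all_pairs_metrics(g, p, spacing)
            assert M.hd95(g, p, spacing) == pytest.approx(hd_o, abs=1e-9)
            assert M.asd(g, p, spacing) == pytest.approx(asd_o, abs=1e-9)

    def test_symmetry(self, rng):
        g = random_mask(rng, (6, 6, 6))
        p = random_mask(rng, (6, 6, 6))
        assert M.hd95(g, p) == pytest.approx(M.hd95(p, g), abs=1e-12)
        assert M.asd(g, p) == pytest.approx(M.asd(p, g), abs=1e-12)

    def test_spacing_scale_equivariance(self, rng):
        g = random_mask(rng, (6, 6, 6))
        p = random_mask(rng, (6, 6, 6))
        s = 2.5
        assert M.hd95(g, p, (s, s, s)) == pytest.approx(s * M.hd95(g, p), rel=1e-12)
        assert M.asd(g, p, (s, s, s)) == pytest.approx(s * M.asd(g, p), rel=1e-12)
        assert M.dice(g, p) == M.dice(g, p)  # spacing-free by construction


class TestAVD:
    def test_identical(self, rng):
        m = random_mask(rng, (5, 5, 5))
        assert M.avd(m, m) == 0.0

    def test_double_volume_is_hundred_percent(self):
        g = np.zeros((6, 6, 6), bool)
        p = np.zeros((6, 6, 6), bool)
        g[0, 0, :2] = True
        p[0, :2, :2] = True
        assert M.avd(g, p) == pytest.approx(100.0)

    def test_known_fraction(self):
        g = np.zeros((4, 4, 4), bool)
        p = np.zeros((4, 4, 4), bool)
        g[:2, :2, :2] = True  # 8 voxels
        p[:2, :2, :2] = True
        p[0, 0, 0] = p[0, 0, 1] = False  # 6 voxels
        assert M.avd(g, p) == pytest.approx(25.0)

    def test_empty_truth_rejected(self):
        with pytest.raises(EmptyStructureError):
            M.avd(np.zeros((3, 3, 3), bool), np.ones((3, 3, 3), bool))


class TestEvaluate:
    def test_perfect_prediction(self, small_phantom):
        _, _, labels = small_phantom
        rep = M.evaluate(labels, labels, [1, 2, 3])
        assert np.allclose(rep.per_class["dice_pct"], 100.0)
        assert np.allclose(rep.per_class["hd95_mm"], 0.0)
        assert np.allclose(rep.per_class["avd_pct"], 0.0)
        assert np.allclose(rep.per_class["asd_mm"], 0.0)
        assert rep.mean_foreground_dice() == pytest.approx(100.0)

    def test_missing_class_flagged_not_zero(self):
        data = np.zeros((4, 4, 4), np.int16)
        data[1, 1, 1] = 1
        truth = M.LabelMap(data)
        pred = M.LabelMap(data.copy())
        rep = M.evaluate(pred, truth, [1, 3])
        row3 = rep.per_class[rep.per_class["class"] == 3].iloc[0]
        assert bool(row3["missing"])
        assert np.isnan(row3["dice_pct"])

    def test_eroded_truth_matches_oracles(self, small_phantom):
        from scipy import ndimage

        _, _, labels = small_phantom
        pred_data = labels.data.copy()
        gm = labels.data == 1
        eroded = ndimage.binary_erosion(gm)
        pred_data[gm & ~eroded] = 0
        pred = M.LabelMap(pred_data, spacing=labels.spacing)
        rep = M.evaluate(pred, labels, [1])
        row = rep.per_class.iloc[0]
        g = labels.data == 1
        p = pred_data == 1
        assert row["dice_pct"] == pytest.approx(M.dice(g, p))
        assert row["avd_pct"] == pytest.approx(M.avd(g, p))
        assert row["dice_pct"] < 100 and row["avd_pct"] > 0

    def test_grid_mismatch_rejected(self):
        a = M.LabelMap(np.zeros((4, 4, 4), np.int16))
        b = M.LabelMap(np.zeros((4, 4, 5), np.int16))
        with pytest.raises(ValueError, match="grid"):
            M.evaluate(a, b, [1])

    def test_dice_avd_consistency(self, rng):
        m = random_mask(rng, (5, 5, 5))
        assert M.dice(m, m) == 100.0 and M.avd(m, m) == 0.0


@settings(derandomize=True, max_examples=60, deadline=None)
@given(seed=st.integers(0, 2 ** 31 - 1), p=st.floats(0.05, 0.95))
def test_dice_bounded_and_symmetric(seed, p):
    rng = np.random.default_rng(seed)
    g = random_mask(rng, (4, 4, 4), p)
    q = random_mask(rng, (4, 4, 4), p)
    d = M.dice(g, q)
    assert 0.0 <= d <= 100.0
    assert d == M.dice(q, g)
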