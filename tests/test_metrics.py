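"""Surface-distance and overlap metrics against exhaustive oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from hypothseg.io import LabelMap
from hypothseg.metrics import (
    average_boundary_distance,
    evaluate_segmentation,
    hard_dice,
    hausdorff_distance,
    paired_signed_rank,
    surface_voxels,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles


def dice_oracle(x, y):
    """Set-counting Dice on explicit voxel coordinate sets."""
    sx = {tuple(p) for p in np.argwhere(x)}
    sy = {tuple(p) for p in np.argwhere(y)}
    if not sx and not sy:
        return 1.0
    if not sx or not sy:
        return 0.0
    return 2 * len(sx & sy) / (len(sx) + len(sy))


def surface_oracle(mask):
    """Enumerate boundary voxels by checking all 6 neighbours explicitly."""
    pts = []
    shape = mask.shape
    for p in np.argwhere(mask):
        for axis in range(3):
            for step in (-1, 1):
                q = p.copy()
                q[axis] += step
                if not (0 <= q[axis] < shape[axis]) or not mask[tuple(q)]:
                    pts.append(p)
                    break
            else:
                continue
            break
    return np.asarray(pts, dtype=float)


def distances_oracle(x, y, voxel_size=(1.0, 1.0, 1.0)):
    """All-pairs (O(n^2)) average boundary and Hausdorff distances."""
    vs = np.asarray(voxel_size)
    sx = surface_oracle(x) * vs
    sy = surface_oracle(y) * vs
    d = cdist(sx, sy)
    directed_means = (d.min(axis=1).mean(), d.min(axis=0).mean())
    directed_maxes = (d.min(axis=1).max(), d.min(axis=0).max())
    return float(np.mean(directed_means)), float(max(directed_maxes))


def _random_mask_pair(rng, max_edge=12):
    shape = tuple(rng.integers(3, max_edge + 1, size=3))
    x = rng.random(shape) < rng.uniform(0.05, 0.5)
    y = rng.random(shape) < rng.uniform(0.05, 0.5)
    return x, y


# ---------------------------------------------------------------------------


class TestHardDice:
    def test_identical_nonempty_masks_give_one(self, rng):
        m = rng.random((7, 7, 7)) < 0.3
        m[3, 3, 3] = True
        assert hard_dice(m, m) == 1.0

    def test_half_overlap(self):
        x = np.zeros((4, 4, 4), bool)
        y = np.zeros((4, 4, 4), bool)
        x[0, 0, :4] = True  # |X| = 4
        y[0, 0, 2:4] = True
        y[1, 0, :2] = True  # |Y| = 4, overlap 2
        assert hard_dice(x, y) == pytest.approx(0.5)

    def test_empty_mask_policy(self):
        e = np.zeros((3, 3, 3), bool)
        f = e.copy()
        f[0, 0, 0] = True
        assert hard_dice(e, e) == 1.0
        assert hard_dice(e, f) == 0.0

    def test_matches_set_counting_oracle(self, rng):
        for _ in range(100):
            x, y = _random_mask_pair(rng)
            assert hard_dice(x, y) == pytest.approx(dice_oracle(x, y), abs=1e-12)


class TestSurfaceVoxels:
    def test_single_voxel_surface_is_itself(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 3, 1] = True
        s = surface_voxels(m)
        np.testing.assert_array_equal(s.points, [[2.0, 3.0, 1.0]])

    def test_solid_cube_has_26_surface_voxels(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        assert len(surface_voxels(m).points) == 26

    def test_points_belong_to_mask_and_match_enumeration(self, rng):
        for _ in range(20):
            x, _ = _random_mask_pair(rng, max_edge=8)
            if not x.any():
                continue
            got = {tuple(p) for p in surface_voxels(x).points}
            assert got == {tuple(p) for p in surface_oracle(x)}
            for p in got:
                assert x[tuple(int(v) for v in p)]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            surface_voxels(np.zeros((3, 3, 3), bool))


class TestSurfaceDistances:
    def test_identical_masks_zero(self, rng):
        m = rng.random((8, 8, 8)) < 0.3
        m[4, 4, 4] = True
        assert average_boundary_distance(m, m) == 0.0
        assert hausdorff_distance(m, m) == 0.0

    def test_two_voxels_three_apart(self):
        x = np.zeros((8, 8, 8), bool)
        y = np.zeros((8, 8, 8), bool)
        x[1, 1, 1] = True
        y[1, 1, 4] = True
        assert average_boundary_distance(x, y) == pytest.approx(3.0)

    def test_hausdorff_dominated_by_furthest_point(self):
        x = np.zeros((8, 8, 8), bool)
        y = np.zeros((8, 8, 8), bool)
        x[0, 0, 0] = True
        y[0, 0, 0] = True
        y[0, 0, 5] = True
        assert hausdorff_distance(x, y) == pytest.approx(5.0)

    def test_against_all_pairs_oracle(self, rng):
        checked = 0
        while checked < 100:
            x, y = _random_mask_pair(rng)
            if not x.any() or not y.any():
                continue
            vs = tuple(rng.choice([1.0, 1.1]) for _ in range(3))
            abd_o, hd_o = distances_oracle(x, y, vs)
            assert average_boundary_distance(x, y, vs) == pytest.approx(abd_o, abs=1e-9)
            assert hausdorff_distance(x, y, vs) == pytest.approx(hd_o, abs=1e-9)
            checked += 1

    def test_avg_distance_bounded_by_hausdorff_and_symmetry(self, rng):
        for _ in range(50):
            x, y = _random_mask_pair(rng, max_edge=8)
            if not x.any() or not y.any():
                continue
            abd = average_boundary_distance(x, y)
            hd = hausdorff_distance(x, y)
            assert abd <= hd + 1e-12
            assert hausdorff_distance(y, x) == pytest.approx(hd)
            assert average_boundary_distance(y, x) == pytest.approx(abd)


class TestEvaluateSegmentation:
    def test_perfect_prediction(self, desk_phantom):
        _, lm = desk_phantom
        report = evaluate_segmentation(lm, lm)
        for row in report.rows:
            assert row["dice"] == 1.0
            assert row["avg_boundary_distance"] == 0.0
            assert row["hausdorff"] == 0.0
        assert not report.undefined

    def test_per_label_rows_match_direct_calls(self, desk_phantom, rng):
        _, gt = desk_phantom
        # corrupt the prediction by erasing one subunit and moving another
        pred_data = gt.data.copy()
        pred_data[pred_data == 2] = 0
        pred = LabelMap(pred_data, gt.taxonomy, gt.voxel_size, gt.affine)
        report = evaluate_segmentation(pred, gt)
        for code in gt.taxonomy.foreground_codes:
            mx, my = pred.data == code, gt.data == code
            row = report[gt.taxonomy.name_of(code)]
            assert row["dice"] == pytest.approx(hard_dice(mx, my))
            if mx.any() and my.any():
                assert row["avg_boundary_distance"] == pytest.approx(
                    average_boundary_distance(mx, my, gt.voxel_size)
                )
                assert row["hausdorff"] == pytest.approx(
                    hausdorff_distance(mx, my, gt.voxel_size)
                )

    def test_empty_structure_flagged_not_zeroed(self, desk_phantom):
        _, gt = desk_phantom
        pred_data = gt.data.copy()
        pred_data[pred_data == 3] = 0
        pred = LabelMap(pred_data, gt.taxonomy, gt.voxel_size, gt.affine)
        report = evaluate_segmentation(pred, gt)
        name = gt.taxonomy.name_of(3)
        assert name in report.undefined
        assert np.isnan(report[name]["avg_boundary_distance"])
        assert report[name]["dice"] == 0.0

    def test_whole_is_union_of_sides(self, desk_phantom):
        _, gt = desk_phantom
        report = evaluate_segmentation(gt, gt)
        names = {r["structure"] for r in report.rows}
        assert {"whole", "whole left", "whole right"} <= names
        assert len(report.rows) == 13  # 10 subunits + 2 sides + whole

    def test_grid_mismatch_raises(self, desk_phantom):
        _, gt = desk_phantom
        small = LabelMap(gt.data[:-2], gt.taxonomy, gt.voxel_size, gt.affine)
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_segmentation(small, gt)


class TestPairedSignedRank:
    def test_large_shift_is_significant(self, rng):
        a = rng.normal(size=10)
        b = a + 5.0
        assert paired_signed_rank(b, a, "greater") < 0.01

    def test_null_is_not_significant_mostly(self, rng):
        hits = 0
        for _ in range(20):
            a = rng.normal(size=12)
            b = a + rng.normal(scale=0.5, size=12)
            if paired_signed_rank(a, b) < 0.05:
                hits += 1
        assert hits <= 4  # about the nominal false-positive rate

    def test_exchanging_samples_reverses_direction(self, rng):
        a = rng.normal(size=8)
        b = a + rng.normal(scale=1.0, size=8)
        assert paired_signed_rank(a, b, "greater") == pytest.approx(
            paired_signed_rank(b, a, "less")
        )

    def test_degenerate_all_zero_differences(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_signed_rank([1.0] * 6, [1.0] * 6)
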