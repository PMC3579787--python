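import numpy as np
import pytest

from _oracles import enumerate_longest_path, grow_pixel_tree, pixel_set_to_mask
from nemameter.skeletonize import (
    SkeletonCycleError,
    SkeletonPath,
    extend_to_edges,
    path_length,
    prune_to_path,
    ratio_filter,
    skeleton_graph,
    smooth_path,
    thin_mask,
)

SQRT2 = np.sqrt(2.0)


class TestThinMask:
    def test_rectangle_thins_to_middle_row(self):
        m = np.zeros((9, 17), bool)
        m[3:6, 3:14] = True  # 3x11 filled rectangle
        sk = thin_mask(m)
        rows, cols = np.nonzero(sk)
        assert set(rows) == {4}
        assert len(cols) >= 7

    def test_one_px_line_unchanged(self):
        m = np.zeros((5, 20), bool)
        m[2, 3:17] = True
        assert np.array_equal(thin_mask(m), m)

    def test_disk_collapses_to_few_pixels(self):
        from skimage.morphology import disk

        sk = thin_mask(np.pad(disk(10), 2).astype(bool))
        assert sk.sum() <= 5

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            thin_mask(np.zeros((5, 5), bool))


class TestPruneToPath:
    def test_straight_line_is_its_own_path(self):
        m = np.zeros((5, 25), bool)
        m[2, 2:23] = True  # 21 pixels
        p = prune_to_path(m)
        assert len(p) == 21
        assert p.length_px == pytest.approx(20.0)
        assert p.prune_ratio == pytest.approx(1.0)

    def test_t_shape_drops_the_stub(self):
        m = np.zeros((10, 25), bool)
        m[6, 2:23] = True  # 21-px horizontal bar, weight 20
        m[0:6, 12] = True  # 6-px vertical stub from its center, weight 6
        p = prune_to_path(m)
        assert p.length_px == pytest.approx(20.0)
        assert p.prune_ratio == pytest.approx(20.0 / 26.0)

    def test_y_shape_keeps_two_longest_arms(self):
        m = np.zeros((25, 25), bool)
        m[12, 2:13] = True   # arm weight 10
        m[12, 13:22] = True  # arm weight 9
        m[13:16, 12] = True  # arm weight 3
        p = prune_to_path(m)
        assert p.length_px == pytest.approx(19.0)
        assert p.prune_ratio == pytest.approx(19.0 / 22.0)

    def test_cycle_raises(self):
        m = np.zeros((7, 7), bool)
        m[1, 1:6] = m[5, 1:6] = True
        m[1:6, 1] = m[1:6, 5] = True  # square ring
        with pytest.raises(SkeletonCycleError):
            prune_to_path(m)

    def test_corner_turn_is_not_a_cycle(self):
        # an L-turn creates a pixel triangle under naive 8-adjacency; the
        # graph construction must suppress the diagonal shortcut instead
        # of rejecting the object
        m = np.zeros((10, 10), bool)
        m[2, 2:7] = True
        m[2:8, 6] = True
        p = prune_to_path(m)
        assert p.prune_ratio == pytest.approx(1.0)

    def test_random_trees_match_enumeration(self, rng):
        # small sample here; 200 trees run in the acceptance suite
        for _ in range(25):
            pts = grow_pixel_tree(rng, int(rng.integers(5, 16)))
            mask = pixel_set_to_mask(pts)
            p = prune_to_path(mask)
            best_w, total_w, _ = enumerate_longest_path(
                set(map(tuple, np.argwhere(mask))))
            assert p.length_px == pytest.approx(best_w, abs=1e-9)
            assert p.prune_ratio == pytest.approx(best_w / total_w, abs=1e-9)

    def test_deterministic_orientation(self):
        m = np.zeros((5, 25), bool)
        m[2, 2:23] = True
        p = prune_to_path(m)
        assert tuple(p.points[0]) < tuple(p.points[-1])


class TestRatioFilter:
    @pytest.mark.parametrize("ratio,minimum,expected", [
        (1.0, 0.8, True), (0.5, 0.8, False), (0.3, 0.0, True),
    ])
    def test_threshold_rule(self, ratio, minimum, expected):
        path = SkeletonPath(points=np.zeros((2, 2)), length_px=1.0,
                            prune_ratio=ratio)
        assert ratio_filter(path, minimum) is expected

    def test_invalid_minimum(self):
        path = SkeletonPath(points=np.zeros((2, 2)), length_px=1.0,
                            prune_ratio=1.0)
        with pytest.raises(ValueError):
            ratio_filter(path, 1.5)


class TestExtendToEdges:
    def test_rectangle_midline_spans_full_width(self):
        mask = np.ones((21, 100), bool)
        pts = np.column_stack([np.full(80, 10.0), np.arange(10.0, 90.0)])
        path = SkeletonPath(pts, path_length(pts), 1.0)
        ext = extend_to_edges(path, mask)
        assert ext.length_px == pytest.approx(99.0, abs=1.0)
        assert ext.points[0][1] < 1.0 and ext.points[-1][1] > 98.0

    def test_path_at_boundary_is_noop(self):
        mask = np.ones((5, 50), bool)
        pts = np.column_stack([np.full(50, 2.0), np.arange(50.0)])
        path = SkeletonPath(pts, path_length(pts), 1.0)
        ext = extend_to_edges(path, mask)
        assert ext.length_px == pytest.approx(path.length_px, abs=1.0)

    def test_phantom_extension_recovers_backbone_length(self, measured_adult):
        _, truth, worm = measured_adult
        assert worm.skeleton_path.length_px == pytest.approx(
            truth.true_length_px, rel=0.03)

    def test_extension_never_shrinks(self, measured_adult):
        _, _, worm = measured_adult
        assert worm.skeleton_path.length_px > 0
        assert worm.skeleton_path.prune_ratio <= 1.0


class TestPathLength:
    def test_horizontal_pixels(self):
        pts = np.column_stack([np.zeros(11), np.arange(11)])
        assert path_length(pts) == pytest.approx(10.0)

    def test_diagonal_pixels(self):
        pts = np.column_stack([np.arange(11), np.arange(11)])
        assert path_length(pts) == pytest.approx(10 * SQRT2)

    def test_mixed_chain_code(self):
        steps = [(0, 1)] * 6 + [(1, 1)] * 5
        pts = np.cumsum(np.array([(0, 0)] + steps), axis=0)
        assert path_length(pts) == pytest.approx(6 + 5 * SQRT2)

    def test_single_point_is_zero(self):
        assert path_length(np.array([[3.0, 4.0]])) == 0.0


class TestSmoothPath:
    def test_endpoints_pinned(self):
        pts = np.cumsum(np.array([(0, 0)] + [(0, 1), (1, 1)] * 10), axis=0)
        sm = smooth_path(SkeletonPath(pts.astype(float), path_length(pts), 1.0))
        assert np.allclose(sm.points[0], pts[0])
        assert np.allclose(sm.points[-1], pts[-1])

    def test_staircase_length_shrinks_toward_chord(self):
        pts = np.cumsum(np.array([(0, 0)] + [(0, 1), (1, 1)] * 20), axis=0)
        path = SkeletonPath(pts.astype(float), path_length(pts), 1.0)
        sm = smooth_path(path)
        chord = np.hypot(*(pts[-1] - pts[0]))
        assert chord <= sm.length_px < path.length_px


def test_skeleton_graph_edge_weights():
    """Orthogonal steps weigh 1, diagonal steps sqrt(2)."""
    m = np.zeros((4, 4), bool)
    m[1, 1], m[1, 2], m[2, 3] = True, True, True
    g = skeleton_graph(m)
    assert g[(1, 1)][(1, 2)]["weight"] == 1.0
    assert g[(1, 2)][(2, 3)]["weight"] == pytest.approx(SQRT2)
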