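import numpy as np
import pytest

from dendrotrace.stacks import GrayStack
from dendrotrace.stitch import (
    TileLayout,
    combine_and_prune,
    layout_to_text,
    nominal_pair_offsets,
    pair_offset,
    parse_layout,
    prune_tree,
    spanning_layout,
)
from dendrotrace.swc import SWCTree
from dendrotrace.synthetic import RenderParams, render_stack
from tests.conftest import SPACING, straight_tube

PAPER_EXAMPLE = "80\n1, 2, 3, 4\n1, 5\n5, 6, 7, 8\n6, 9\n9\n"


class TestParseLayout:
    def test_documented_example(self):
        layout = parse_layout(PAPER_EXAMPLE)
        assert layout.overlap_pct == 80
        assert layout.rows == [[1, 2, 3, 4], [5, 6, 7, 8], [9]]
        assert layout.row_links == [(1, 5), (6, 9)]

    def test_single_tile_layout(self):
        layout = parse_layout("100\n1\n")
        assert layout.tiles == [1] and layout.row_links == []
        assert layout.adjacent_pairs() == []

    def test_unknown_tile_in_link_rejected(self):
        with pytest.raises(ValueError):
            parse_layout("80\n1, 2\n1, 7\n3, 4\n")

    def test_malformed_number_reports_line(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_layout("80\n1, x, 3\n")

    def test_round_trip_through_text(self):
        layout = parse_layout(PAPER_EXAMPLE)
        again = parse_layout(layout_to_text(layout))
        assert again.rows == layout.rows
        assert again.row_links == layout.row_links
        assert again.overlap_pct == layout.overlap_pct

    def test_adjacent_pairs_cover_rows_and_links(self):
        layout = parse_layout(PAPER_EXAMPLE)
        pairs = layout.adjacent_pairs()
        assert (1, 2) in pairs and (5, 6) in pairs and (1, 5) in pairs and (6, 9) in pairs


class TestPairOffset:
    def shifted_tiles(self, shift):
        """Tile B shows the same scene offset by `shift` = (dx, dy)."""
        rng = np.random.default_rng(0)
        scene = rng.uniform(0.3, 1.0, (4, 96, 160))
        dx, dy = shift
        a = GrayStack(scene[:, :, :96].copy() / scene.max(), SPACING)
        b = GrayStack(scene[:, :, dx : dx + 96].copy() / scene.max(), SPACING)
        return a, b

    def test_self_shift_recovered_exactly(self):
        a, b = self.shifted_tiles((17, 0))
        off, w = pair_offset(a, b, (20, 0, 0), search_margin=8)
        assert off == (17, 0, 0)
        assert w > 0.2

    def test_identical_tiles_zero_offset_high_weight(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.2, 1.0, (4, 64, 64))
        a = GrayStack(v / v.max(), SPACING)
        b = GrayStack(v.copy() / v.max(), SPACING)
        off, w = pair_offset(a, b, (0, 0, 0), search_margin=5)
        assert off == (0, 0, 0)
        assert w > 0.8

    def test_uncorrelated_noise_low_weight(self):
        rng = np.random.default_rng(2)
        a = GrayStack(rng.uniform(size=(4, 64, 64)), SPACING)
        b = GrayStack(rng.uniform(size=(4, 64, 64)), SPACING)
        _, w = pair_offset(a, b, (0, 0, 0), search_margin=5)
        assert w < 0.2

    def test_constant_overlap_keeps_nominal_weight_zero(self):
        a = GrayStack(np.full((2, 64, 64), 0.5), SPACING)
        b = GrayStack(np.full((2, 64, 64), 0.5), SPACING)
        off, w = pair_offset(a, b, (10, 0, 0), search_margin=5)
        assert off == (10, 0, 0) and w == 0.0


class TestSpanningLayout:
    def test_chain_accumulates_offsets(self):
        layout = TileLayout([1, 2, 3], [[1, 2, 3]], [], 80.0)
        layout.pair_offsets = {(1, 2): ((10, 0, 0), 0.9), (2, 3): ((10, 0, 0), 0.9)}
        spanning_layout(layout)
        assert layout.global_xy == {1: (0.0, 0.0), 2: (10.0, 0.0), 3: (20.0, 0.0)}

    def test_inconsistent_low_weight_edge_excluded(self):
        layout = TileLayout([1, 2, 3], [[1, 2, 3]], [], 80.0)
        layout.pair_offsets = {
            (1, 2): ((10, 0, 0), 0.9),
            (2, 3): ((10, 0, 0), 0.8),
            (1, 3): ((25, 0, 0), 0.1),  # inconsistent, weak
        }
        spanning_layout(layout)
        assert layout.global_xy[3] == (20.0, 0.0)  # via 1-2-3, not the bad edge

    def test_two_tiles_single_edge(self):
        layout = TileLayout([1, 2], [[1, 2]], [], 80.0)
        layout.pair_offsets = {(1, 2): ((7, -3, 0), 0.5)}
        spanning_layout(layout)
        assert layout.global_xy[2] == (7.0, -3.0)

    def test_disconnected_graph_reports_components(self):
        layout = TileLayout([1, 2, 3, 4], [[1, 2], [3, 4]], [], 80.0)
        layout.pair_offsets = {(1, 2): ((5, 0, 0), 0.9), (3, 4): ((5, 0, 0), 0.9)}
        with pytest.raises(ValueError, match="disconnected"):
            spanning_layout(layout)

    def test_gauge_invariance_of_relative_positions(self):
        layout = TileLayout([1, 2, 3], [[1, 2, 3]], [], 80.0)
        layout.pair_offsets = {(1, 2): ((10, 2, 0), 0.9), (2, 3): ((11, -1, 0), 0.9)}
        spanning_layout(layout)
        rel = np.array(layout.global_xy[3]) - np.array(layout.global_xy[2])
        shifted = TileLayout([1, 2, 3], [[1, 2, 3]], [], 80.0)
        shifted.pair_offsets = {(1, 2): ((10, 2, 0), 0.9), (2, 3): ((11, -1, 0), 0.9)}
        spanning_layout(shifted)
        rel2 = np.array(shifted.global_xy[3]) - np.array(shifted.global_xy[2])
        np.testing.assert_array_equal(rel, rel2)


class TestPruneTree:
    def chain(self, tree, coords, r=0.8):
        prev = None
        for x, y in coords:
            prev = tree.add(3, x, y, 8.0, r, parent=prev.id if prev else -1)
        return prev

    def test_short_isolated_fragment_deleted_long_kept(self):
        tree = SWCTree()
        self.chain(tree, [(x, 5.0) for x in np.arange(0, 16, 1.0)])   # 15 um
        self.chain(tree, [(x, 30.0) for x in np.arange(0, 26, 1.0)])  # 25 um
        prune_tree(tree)
        ys = {p.y for p in tree.points}
        assert ys == {30.0}

    def test_small_twig_deleted_larger_side_branch_kept(self):
        tree = SWCTree()
        trunk_end = self.chain(tree, [(x, 10.0) for x in np.arange(0, 30, 1.0)])
        mid = [p for p in tree.points if p.x == 14.0][0]
        # 3-point twig
        prev = mid
        for y in (11.0, 12.0, 13.0):
            prev = tree.add(3, 14.0, y, 8.0, 0.5, parent=prev.id)
        # 6-point side branch at another trunk point
        mid2 = [p for p in tree.points if p.x == 20.0][0]
        prev = mid2
        for y in np.arange(11.0, 17.0, 1.0):
            prev = tree.add(3, 20.0, float(y), 8.0, 0.5, parent=prev.id)
        prune_tree(tree)
        assert not any(p.x == 14.0 and p.y > 10.0 for p in tree.points)
        assert sum(1 for p in tree.points if p.x == 20.0 and p.y > 10.0) == 6

    def test_pruning_is_idempotent(self):
        rng = np.random.default_rng(3)
        tree = SWCTree()
        for _ in range(6):
            n = int(rng.integers(2, 30))
            x0, y0 = rng.uniform(0, 80, 2)
            ang = rng.uniform(0, 2 * np.pi)
            self.chain(tree, [(x0 + k * np.cos(ang), y0 + k * np.sin(ang)) for k in range(n)])
        once = prune_tree(tree.copy())
        twice = prune_tree(once.copy())
        assert [(p.id, p.parent) for p in twice] == [(p.id, p.parent) for p in once]

    def test_soma_scale_points_exempt(self):
        tree = SWCTree()
        a = tree.add(1, 5.0, 5.0, 8.0, 4.0)
        tree.add(1, 6.0, 5.0, 8.0, 3.5, parent=a.id)
        prune_tree(tree)
        assert len(tree) == 2


class TestCombineAndPrune:
    def test_tube_spanning_two_tiles_yields_single_component(self):
        # one tube rendered once, cropped into two overlapping tiles,
        # each tile traced as the tube portion it sees
        dx = SPACING[0]
        shift_px = 80
        left = SWCTree()
        prev = None
        for x in np.arange(2.0, 24.0, 1.5):
            prev = left.add(3, float(x), 12.8, 8.0, 0.8, parent=prev.id if prev else -1)
        right = SWCTree()
        prev = None
        for x in np.arange(2.0, 24.0, 1.5):  # same tube in tile-2 frame
            xl = x + shift_px * dx
            if xl < 26.0:
                continue
            prev = right.add(3, float(x), 12.8, 8.0, 0.8, parent=prev.id if prev else -1)
        layout = TileLayout([1, 2], [[1, 2]], [], 80.0)
        layout.pair_offsets = {(1, 2): ((shift_px, 0, 0), 0.9)}
        spanning_layout(layout)
        tree = combine_and_prune({1: left, 2: right}, layout, SPACING, (32, 128, 128))
        assert len(tree.components()) == 1
        xs = sorted(p.x for p in tree.points)
        gaps = np.diff(xs)
        assert all(g > 0.3 for g in gaps if g > 0)  # no stacked duplicates
        tree.validate()

    def test_empty_input_gives_empty_tree(self):
        tree = combine_and_prune({}, TileLayout([], [], [], 80.0), SPACING)
        assert len(tree) == 0

    def test_root_is_largest_radius_soma(self):
        t1 = SWCTree()
        prev = None
        for x in np.arange(0, 30, 1.0):
            prev = t1.add(3, float(x), 5.0, 8.0, 0.8 if x != 10.0 else 2.5, parent=prev.id if prev else -1)
        layout = TileLayout([1], [[1]], [], 80.0)
        layout.global_xy = {1: (0.0, 0.0)}
        tree = combine_and_prune({1: t1}, layout, SPACING)
        root = [p for p in tree.points if p.parent == -1]
        assert len(root) == 1
        assert root[0].radius == pytest.approx(2.5)
        assert root[0].type == 1
        assert sorted(p.id for p in tree.points) == list(range(1, len(tree) + 1))
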