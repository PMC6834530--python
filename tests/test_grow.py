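import itertools

import numpy as np
import pytest

from dendrotrace.centerline import TracePoint
from dendrotrace.config import PipelineConfig
from dendrotrace.grow import (
    GrowParams,
    OccupancyGrid,
    absorb_redundant,
    connect_ends,
    extend_from_end,
    is_occupied,
    mark_occupied,
    recover_thick,
    weighted_shortest_path,
)
from dendrotrace.stacks import GrayStack, min_projection, subtract_background
from dendrotrace.swc import SWCTree, read_swc
from dendrotrace.synthetic import RenderParams, render_stack
from tests.conftest import SPACING, straight_tube


def brute_force_grid_distance(img, src, target):
    """Exhaustive Dijkstra-free shortest path by relaxation to convergence."""
    h, w = img.shape
    dist = {(y, x): np.inf for y in range(h) for x in range(w)}
    dist[src] = 0.0
    for _ in range(h * w):
        changed = False
        for (y, x), d in list(dist.items()):
            for dy, dx in itertools.product((-1, 0, 1), repeat=2):
                if dy == 0 and dx == 0:
                    continue
                v = (y + dy, x + dx)
                if not (0 <= v[0] < h and 0 <= v[1] < w):
                    continue
                step = np.sqrt(2) if dy and dx else 1.0
                nd = d + 0.5 * (img[y, x] + img[v]) * step
                if nd < dist[v] - 1e-15:
                    dist[v] = nd
                    changed = True
        if not changed:
            break
    return dist[target]


class TestMarkOccupied:
    def grid(self):
        return OccupancyGrid.for_stack((32, 64, 64), SPACING)

    def test_degenerate_capsule_is_ball(self):
        g = self.grid()
        p = TracePoint(6.4, 6.4, 8.0, 1.0)
        mark_occupied(g, p)
        assert is_occupied(g, p)
        count = g.voxels.sum()
        expected = 4 / 3 * np.pi * 1.0**3 / (0.2 * 0.2 * 0.5)
        assert count == pytest.approx(expected, rel=0.30)

    def test_straight_cylinder_volume(self):
        g = self.grid()
        p = TracePoint(2.0, 6.4, 8.0, 1.0)
        q = TracePoint(10.0, 6.4, 8.0, 1.0)
        mark_occupied(g, p, q)
        count = g.voxels.sum()
        # cylinder pi r^2 L plus two hemispherical caps
        expected = (np.pi * 1.0**2 * 8.0 + 4 / 3 * np.pi) / (0.2 * 0.2 * 0.5)
        assert count == pytest.approx(expected, rel=0.15)

    def test_marking_twice_is_idempotent(self):
        g = self.grid()
        p = TracePoint(4.0, 4.0, 8.0, 0.8)
        q = TracePoint(6.0, 4.0, 8.0, 1.2)
        mark_occupied(g, p, q)
        once = g.voxels.copy()
        mark_occupied(g, p, q)
        np.testing.assert_array_equal(g.voxels, once)


class TestWeightedShortestPath:
    def test_uniform_image_straight_line_cost(self):
        img = np.full((11, 11), 0.5)
        dists, path, _ = weighted_shortest_path(img, (5, 0), [(5, 10)])
        assert dists[(5, 10)] == pytest.approx(0.5 * 10.0)
        assert all(p[0] == 5 for p in path)

    def test_path_follows_dark_channel(self):
        img = np.full((11, 11), 0.9)
        img[2, :] = 0.05  # dark channel off the straight line
        img[2:9, 0] = 0.05
        img[2:9, 10] = 0.05
        dists, path, _ = weighted_shortest_path(img, (8, 0), [(8, 10)])
        assert any(p[0] == 2 for p in path)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_small_grids(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0.05, 1.0, (5, 5))
        src, target = (0, 0), (4, 3)
        dists, _, _ = weighted_shortest_path(img, src, [target])
        assert dists[target] == pytest.approx(brute_force_grid_distance(img, src, target), abs=1e-9)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            weighted_shortest_path(np.ones((4, 4)), (0, 0), [(9, 9)])


class TestExtendFromEnd:
    def test_truncated_tube_recovered(self):
        """An end point mid-tube grows out to at least 90% of the rest."""
        tube = straight_tube(1.0, x0=1.5, x1=24.0)
        stack, _ = render_stack(tube, (32, 128, 128), SPACING, RenderParams(seed=2))
        # trace only the left half as a seed chain
        tree = SWCTree()
        prev = None
        for x in (2.0, 4.0, 6.0, 8.0, 10.0):
            prev = tree.add(3, x, 12.8, 8.0, 1.0, parent=prev.id if prev else -1)
        grid = OccupancyGrid.for_stack(stack.shape, SPACING)
        byid = tree.by_id()
        for p in tree.points:
            mark_occupied(grid, p, byid[p.parent]) if p.parent != -1 else mark_occupied(grid, p)
        extend_from_end(stack, tree, grid, GrowParams())
        max_x = max(p.x for p in tree.points)
        assert max_x >= 10.0 + 0.9 * (24.0 - 10.0) - 1.0

    def test_terminal_in_blank_field_stops(self):
        stack = GrayStack(np.full((16, 64, 64), 0.95), SPACING)
        tree = SWCTree()
        a = tree.add(3, 4.0, 6.4, 4.0, 0.8)
        tree.add(3, 6.0, 6.4, 4.0, 0.8, parent=a.id)
        grid = OccupancyGrid.for_stack(stack.shape, SPACING)
        n_before = len(tree)
        extend_from_end(stack, tree, grid, GrowParams())
        assert len(tree) == n_before

    def test_two_fragments_of_one_tube_join_without_duplicates(self):
        tube = straight_tube(1.0, x0=1.5, x1=24.0)
        stack, _ = render_stack(tube, (32, 128, 128), SPACING, RenderParams(seed=2))
        tree = SWCTree()
        prev = None
        for x in (2.0, 4.0, 6.0):
            prev = tree.add(3, x, 12.8, 8.0, 1.0, parent=prev.id if prev else -1)
        prev = None
        for x in (18.0, 20.0, 22.0):
            prev = tree.add(3, x, 12.8, 8.0, 1.0, parent=prev.id if prev else -1)
        grid = OccupancyGrid.for_stack(stack.shape, SPACING)
        byid = tree.by_id()
        for p in tree.points:
            mark_occupied(grid, p, byid[p.parent]) if p.parent != -1 else mark_occupied(grid, p)
        extend_from_end(stack, tree, grid, GrowParams())
        connect_ends(tree, GrowParams())
        assert len(tree.components()) == 1
        xs = sorted(p.x for p in tree.points)
        assert all(b - a > 0.15 for a, b in zip(xs, xs[1:]) if b - a > 0)


class TestRecoverThick:
    def test_fully_traced_scene_adds_nothing(self):
        tube = straight_tube(1.0)
        stack, _ = render_stack(tube, (32, 128, 128), SPACING, RenderParams(seed=3))
        tree = SWCTree()
        prev = None
        for x in np.arange(2.0, 24.0, 2.0):
            prev = tree.add(3, float(x), 12.8, 8.0, 1.0, parent=prev.id if prev else -1)
        proj = subtract_background(min_projection(stack), 20.0)
        assert recover_thick(stack, proj, tree, GrowParams()) == []

    def test_untraced_dark_blob_recovered_with_matching_radius(self):
        soma = SWCTree()
        a = soma.add(1, 8.0, 12.8, 8.0, 3.0)
        soma.add(1, 8.2, 12.8, 8.0, 3.0, parent=a.id)
        stack, _ = render_stack(soma, (32, 128, 128), SPACING, RenderParams(seed=4))
        # an empty trace elsewhere in the field
        tree = SWCTree()
        p = tree.add(3, 20.0, 3.0, 8.0, 0.5)
        tree.add(3, 21.0, 3.0, 8.0, 0.5, parent=p.id)
        proj = subtract_background(min_projection(stack), 20.0)
        chains = recover_thick(stack, proj, tree, GrowParams())
        pts = [c for ch in chains for c in ch]
        assert pts, "soma blob not recovered"
        largest = max(p.radius for p in pts)
        assert largest == pytest.approx(3.0, rel=0.30)

    def test_already_covered_soma_not_duplicated(self):
        soma = SWCTree()
        a = soma.add(1, 8.0, 12.8, 8.0, 3.0)
        soma.add(1, 8.2, 12.8, 8.0, 3.0, parent=a.id)
        stack, _ = render_stack(soma, (32, 128, 128), SPACING, RenderParams(seed=4))
        tree = SWCTree()
        p = tree.add(1, 8.0, 12.8, 8.0, 3.0)
        tree.add(1, 8.2, 12.8, 8.0, 3.0, parent=p.id)
        proj = subtract_background(min_projection(stack), 20.0)
        assert recover_thick(stack, proj, tree, GrowParams()) == []


class TestConnectEnds:
    def chain(self, tree, xs, y, r=0.8, z=8.0):
        prev = None
        for x in xs:
            prev = tree.add(3, x, y, z, r, parent=prev.id if prev else -1)

    def test_collinear_fragments_bridge_small_gap(self):
        tree = SWCTree()
        self.chain(tree, [2, 4, 6], 10.0)
        self.chain(tree, [9, 11, 13], 10.0)  # 3 um gap
        connect_ends(tree, GrowParams())
        assert len(tree.components()) == 1
        tree.validate()

    def test_depth_gate_blocks_connection(self):
        tree = SWCTree()
        self.chain(tree, [2, 4, 6], 10.0, z=2.0)
        self.chain(tree, [8, 10, 12], 10.0, z=10.0)  # dz 8 > 5
        connect_ends(tree, GrowParams())
        assert len(tree.components()) == 2

    def test_already_connected_pair_not_cycled(self):
        tree = read_swc("1 3 0 0 0 1 -1\n2 3 2 0 0 1 1\n3 3 4 0 0 1 2\n")
        connect_ends(tree, GrowParams())
        tree.validate()
        assert sum(1 for p in tree.points if p.parent == -1) == 1

    def test_interpolates_points_across_wide_gap(self):
        tree = SWCTree()
        self.chain(tree, [2, 3, 4], 10.0, r=0.5)
        self.chain(tree, [8.5, 9.5, 10.5], 10.0, r=0.5)  # 4.5 um gap > r_a+r_b
        n0 = len(tree)
        connect_ends(tree, GrowParams())
        assert len(tree.components()) == 1
        assert len(tree) > n0  # bridging points added
        tree.validate()


class TestAbsorbRedundant:
    def test_small_point_inside_soma_ball_absorbed(self):
        tree = SWCTree()
        soma = tree.add(1, 10.0, 10.0, 8.0, 3.0)
        ring = tree.add(3, 11.0, 10.5, 8.0, 0.5)  # inside the soma ball
        child = tree.add(3, 14.5, 10.0, 8.0, 0.5, parent=ring.id)
        absorb_redundant(tree)
        ids = {p.id for p in tree.points}
        assert ring.id not in ids and soma.id in ids
        assert tree.by_id()[child.id].parent == soma.id
        tree.validate()

    def test_thin_chains_untouched(self):
        tree = SWCTree()
        prev = None
        for x in np.arange(0, 10, 1.0):
            prev = tree.add(3, float(x), 5.0, 8.0, 0.6, parent=prev.id if prev else -1)
        n0 = len(tree)
        absorb_redundant(tree)
        assert len(tree) == n0
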