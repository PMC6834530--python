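import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendrotrace.centerline import (
    DepthSeam,
    TracePoint,
    XYPath,
    depth_seam,
    distance_map,
    link_points,
    place_points,
    refine_z,
    skeletonize_and_split,
    z_image,
)
from dendrotrace.stacks import GrayStack

SP3 = (0.2, 0.2, 0.5)


def brute_force_seam(z_img: np.ndarray, step: int) -> float:
    """Exhaustive minimum over all monotone left-right seams."""
    L, D = z_img.shape
    best = [np.inf]

    def rec(i, z, cost):
        cost += z_img[i, z]
        if cost >= best[0]:
            return
        if i == L - 1:
            best[0] = cost
            return
        for nz in range(max(0, z - step), min(D, z + step + 1)):
            rec(i + 1, nz, cost)

    for z0 in range(D):
        rec(0, z0, 0.0)
    return best[0]


class TestSkeletonizeAndSplit:
    def test_straight_bar_gives_one_axial_path(self):
        mask = np.zeros((32, 32), bool)
        mask[14:19, 4:28] = True
        paths = skeletonize_and_split(mask)
        long_paths = [p for p in paths if len(p) > 3]
        assert len(long_paths) == 1
        ys = {px[0] for px in long_paths[0].pixels}
        assert ys <= {15, 16, 17}

    def test_plus_shape_gives_four_paths_at_one_junction(self):
        mask = np.zeros((41, 41), bool)
        mask[18:23, 2:39] = True
        mask[2:39, 18:23] = True
        paths = skeletonize_and_split(mask)
        long_paths = [p for p in paths if len(p) >= 5]
        assert len(long_paths) == 4
        junction_ends = [p for path in long_paths for p in path.end_kind if p == "junction"]
        assert len(junction_ends) >= 4

    def test_empty_mask_gives_no_paths(self):
        assert skeletonize_and_split(np.zeros((8, 8), bool)) == []

    def test_consecutive_pixels_are_8_neighbors_no_repeats(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((48, 48), bool)
        mask[10:14, 5:44] = True
        mask[10:40, 20:24] = True
        for path in skeletonize_and_split(mask):
            seen = set()
            for a, b in zip(path.pixels, path.pixels[1:]):
                assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1
            interior = path.pixels[1:-1]
            assert len(set(interior)) == len(interior)

    def test_isolated_blob_yields_single_pixel_path(self):
        mask = np.zeros((16, 16), bool)
        mask[6:10, 6:10] = True
        paths = skeletonize_and_split(mask)
        assert len(paths) == 1 and len(paths[0]) >= 1


class TestDistanceMap:
    def test_disk_center_close_to_radius(self):
        mask = np.zeros((41, 41), bool)
        ys, xs = np.mgrid[0:41, 0:41] - 20
        mask[np.hypot(xs, ys) <= 10] = True
        dmap = distance_map(mask, (0.2, 0.2))
        assert dmap[20, 20] == pytest.approx(10 * 0.2, rel=0.12)

    def test_boundary_pixel_within_one_pixel(self):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        dmap = distance_map(mask, (0.2, 0.2))
        assert dmap[4, 8] <= 0.2 + 1e-9

    def test_matches_bruteforce_nearest_background(self):
        rng = np.random.default_rng(7)
        mask = rng.random((20, 20)) < 0.6
        dmap = distance_map(mask, (0.3, 0.3))
        bg = np.argwhere(~mask)
        for y, x in np.argwhere(mask)[::7]:
            d = np.min(np.hypot((bg[:, 0] - y) * 0.3, (bg[:, 1] - x) * 0.3)) if len(bg) else np.inf
            assert dmap[y, x] == pytest.approx(d, abs=1e-9)


class TestZImage:
    def test_shape_is_positions_by_depth(self):
        stack = GrayStack(np.random.default_rng(0).uniform(size=(6, 16, 16)), SP3)
        path = XYPath([(4, x) for x in range(3, 12)])
        assert z_image(stack, path).shape == (9, 6)

    def test_tube_at_constant_depth_is_dark_column(self):
        v = np.full((8, 16, 16), 0.9)
        v[5, 7, :] = 0.2
        stack = GrayStack(v / v.max(), SP3)
        img = z_image(stack, XYPath([(7, x) for x in range(16)]))
        assert np.all(img.argmin(axis=1) == 5)

    def test_single_pixel_path(self):
        v = np.random.default_rng(1).uniform(0.1, 1.0, (5, 8, 8))
        stack = GrayStack(v / v.max(), SP3)
        img = z_image(stack, XYPath([(2, 3)]))
        np.testing.assert_array_equal(img[0], stack.voxels[:, 2, 3])

    def test_out_of_bounds_path_rejected(self):
        stack = GrayStack(np.ones((4, 8, 8)), SP3)
        with pytest.raises(IndexError):
            z_image(stack, XYPath([(7, 9)]))


class TestDepthSeam:
    def test_constant_band_is_followed(self):
        img = np.full((10, 6), 0.9)
        img[:, 3] = 0.1
        seam = depth_seam(img, 2)
        assert np.all(seam.z_index == 3)

    def test_one_plane_per_column_ramp_followed(self):
        img = np.full((6, 8), 0.9)
        for i in range(6):
            img[i, i + 1] = 0.1
        seam = depth_seam(img, 2)
        np.testing.assert_array_equal(seam.z_index, np.arange(1, 7))

    @given(st.integers(0, 2**31 - 1), st.integers(2, 8), st.integers(2, 8), st.integers(1, 3))
    @settings(max_examples=30, deadline=None)
    def test_cost_matches_exhaustive_enumeration(self, seed, L, D, step):
        img = np.random.default_rng(seed).uniform(size=(L, D))
        seam = depth_seam(img, step)
        assert seam.cost == pytest.approx(brute_force_seam(img, step), abs=1e-9)
        assert np.all(np.abs(np.diff(seam.z_index)) <= step)

    def test_ties_break_toward_smaller_z(self):
        img = np.zeros((4, 5))
        seam = depth_seam(img, 2)
        assert np.all(seam.z_index == 0)


class TestPlacePoints:
    def make_path(self, n):
        return XYPath([(10, x) for x in range(n)])

    def test_uniform_tube_spacing_roughly_sum_of_radii(self):
        # 1 um radius, 10 um path -> gaps ~2 um -> about 6 points
        path = self.make_path(51)  # 50 steps * 0.2 um = 10 um
        dmap = np.full((21, 51), 1.0)
        seam = DepthSeam(np.full(51, 16), 0.0)
        pts = place_points(path, dmap, seam, SP3)
        assert 5 <= len(pts) <= 7
        gaps = [np.linalg.norm(b.xyz - a.xyz) for a, b in zip(pts, pts[1:])]
        assert all(1.8 <= g <= 2.6 for g in gaps[:-1])

    def test_short_path_single_point(self):
        path = self.make_path(2)
        dmap = np.full((21, 2), 2.0)
        pts = place_points(path, dmap, DepthSeam(np.zeros(2, int), 0.0), SP3)
        assert len(pts) >= 1

    def test_rapid_radius_change_halves_spacing(self):
        path = self.make_path(51)
        dmap = np.full((21, 51), 1.0)
        dmap[:, 25:] = 0.3  # step change
        seam = DepthSeam(np.zeros(51, int), 0.0)
        pts = place_points(path, dmap, seam, SP3)
        idx = [i for i, p in enumerate(pts) if abs(p.x - 25 * 0.2) < 1.5]
        xs = sorted(p.x for p in pts)
        gaps = np.diff(xs)
        near_step = [g for x, g in zip(xs, gaps) if 4.0 < x < 6.0]
        assert near_step and min(near_step) < 1.3  # < r_a + r_b at the step


class TestRefineZ:
    def make_stack(self, z_dark):
        v = np.full((16, 8, 8), 0.9)
        v[z_dark, 4, 4] = 0.2
        return GrayStack(v / v.max(), SP3)

    def test_already_at_minimum_unchanged(self):
        stack = self.make_stack(8)
        z = refine_z(stack, TracePoint(0.8, 0.8, 8 * 0.5, 1.0), 3)
        assert z == pytest.approx(8 * 0.5)

    def test_moves_to_nearby_minimum(self):
        stack = self.make_stack(6)
        z = refine_z(stack, TracePoint(0.8, 0.8, 8 * 0.5, 1.0), 3)
        assert z == pytest.approx(6 * 0.5)

    def test_flat_profile_stays_put(self):
        v = np.full((16, 8, 8), 0.5)
        stack = GrayStack(v, SP3)
        z = refine_z(stack, TracePoint(0.8, 0.8, 5 * 0.5, 1.0), 3)
        assert z == pytest.approx(5 * 0.5)


class TestLinkPoints:
    def mk(self, coords, r=1.0):
        return [TracePoint(x, y, z, r) for x, y, z in coords]

    def test_collinear_points_form_single_chain(self):
        pts = self.mk([(0, 0, 0), (2, 0, 0), (4, 0, 0), (6, 0, 0)])
        assert link_points(pts) == [-1, 0, 1, 2]

    def test_sharp_kink_breaks_chain(self):
        pts = self.mk([(0, 0, 0), (2, 0, 0), (0.5, 1.0, 0)])  # ~147 degree turn
        parents = link_points(pts, max_angle_deg=90)
        assert parents[2] == -1

    def test_large_dz_not_linked(self):
        pts = self.mk([(0, 0, 0), (2, 0, 8.0)])
        assert link_points(pts, max_dz_um=5.0)[1] == -1

    def test_large_gap_not_linked_for_thin_points(self):
        pts = self.mk([(0, 0, 0), (7, 0, 0)], r=0.5)
        assert link_points(pts, max_gap_um=5.0)[1] == -1

    def test_thick_points_link_at_natural_spacing(self):
        pts = self.mk([(0, 0, 0), (6, 0, 0)], r=3.0)
        assert link_points(pts, max_gap_um=5.0)[1] == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_is_forest_respecting_gates(self, seed):
        rng = np.random.default_rng(seed)
        pts = [TracePoint(*rng.uniform(0, 20, 3), float(rng.uniform(0.3, 1.5))) for _ in range(12)]
        parents = link_points(pts, 5.0, 100.0, 5.0)
        for i, par in enumerate(parents):
            assert par in (-1, i - 1)
            if par != -1:
                gap = float(np.linalg.norm(pts[i].xyz - pts[par].xyz))
                assert gap <= max(5.0, 1.5 * (pts[i].radius + pts[par].radius)) + 1e-9
                assert abs(pts[i].z - pts[par].z) <= 5.0 + 1e-9
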