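"""From binary mask to candidate SWC points.

The mask is thinned to a one-pixel skeleton and dissected into
"xy-paths": segments running between endpoints and/or junction pixels.
Radii come from the Euclidean distance map of the mask; depth comes from
a "z-image" (the stack cut vertically along the path) through which a
left-to-right minimal-intensity seam is traced by dynamic programming.
Points are placed along each path at spacing roughly the sum of adjacent
radii, and linked into chains unless the gap, the turning angle or the
depth jump exceeds user thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import distance_transform_edt, gaussian_filter1d
from skimage.morphology import skeletonize

__all__ = [
    "XYPath",
    "DepthSeam",
    "TracePoint",
    "skeletonize_and_split",
    "distance_map",
    "z_image",
    "depth_seam",
    "place_points",
    "refine_z",
    "link_points",
]

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class XYPath:
    """An ordered skeleton segment between endpoints and/or junctions.

    ``pixels`` is a list of (y, x) integer positions; consecutive pixels
    are 8-neighbors and none repeats.  ``end_kind`` labels each terminus
    as ``"endpoint"`` or ``"junction"``.
    """

    pixels: list[tuple[int, int]]
    end_kind: tuple[str, str] = ("endpoint", "endpoint")

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class DepthSeam:
    """One z index per path position plus the accumulated seam intensity."""

    z_index: np.ndarray
    cost: float


@dataclass
class TracePoint:
    """A candidate morphology point in physical coordinates (micrometres)."""

    x: float
    y: float
    z: float
    radius: float
    valid: bool = True

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def skeletonize_and_split(mask) -> list[XYPath]:
    """Thin the mask and dissect the skeleton into xy-paths.

    Skeleton pixels with >= 3 skeleton neighbors are junctions; paths run
    between endpoints/junctions and every non-junction skeleton pixel
    belongs to exactly one path (junction pixels may terminate several).
    Pure cycles (no node pixel) are opened at an arbitrary pixel.
    """
    pixels = mask.pixels if hasattr(mask, "pixels") else np.asarray(mask, dtype=bool)
    if not pixels.any():
        return []
    skel = skeletonize(pixels)
    deg = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8), mode="constant")
    deg = (deg - 1) * skel  # neighbor count at skeleton pixels
    ys, xs = np.nonzero(skel)
    nodes = {(y, x) for y, x in zip(ys, xs) if deg[y, x] != 2}

    def neighbors(p):
        y, x = p
        for dy, dx in _NEIGH:
            q = (y + dy, x + dx)
            if 0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1] and skel[q]:
                yield q

    def kind(p):
        return "junction" if deg[p] >= 3 else "endpoint"

    paths: list[XYPath] = []
    used_edges: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    visited_mid: set[tuple[int, int]] = set()

    for node in sorted(nodes):
        # an isolated compact blob thins to a single pixel; keep it as a
        # one-pixel path so it can still seed a point (e.g. one bead)
        if deg[node] == 0:
            paths.append(XYPath([node], ("endpoint", "endpoint")))
            continue
        for nb in neighbors(node):
            if (node, nb) in used_edges:
                continue
            path = [node]
            prev, cur = node, nb
            used_edges.add((node, nb))
            while True:
                path.append(cur)
                if cur in nodes:
                    used_edges.add((cur, prev))
                    break
                visited_mid.add(cur)
                nxt = [q for q in neighbors(cur) if q != prev and (q in nodes or q not in visited_mid)]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
            if len(path) >= 2:
                paths.append(XYPath(path, (kind(path[0]), kind(path[-1]) if path[-1] in nodes else "endpoint")))

    # pure cycles: remaining degree-2 pixels not visited
    remaining = {(y, x) for y, x in zip(ys, xs)} - visited_mid - nodes
    while remaining:
        start = min(remaining)
        path = [start]
        remaining.discard(start)
        cur, prev = start, None
        while True:
            nxt = [q for q in neighbors(cur) if q in remaining]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
            remaining.discard(cur)
        if len(path) >= 2:
            paths.append(XYPath(path, ("endpoint", "endpoint")))
    return paths


def distance_map(mask, spacing: tuple[float, float]) -> np.ndarray:
    """Euclidean distance (μm) from each in-mask pixel to the mask boundary."""
    pixels = mask.pixels if hasattr(mask, "pixels") else np.asarray(mask, dtype=bool)
    dx, dy = spacing
    return distance_transform_edt(pixels, sampling=(dy, dx))


def z_image(stack, path: XYPath) -> np.ndarray:
    """Cut the stack vertically along an xy-path.

    Returns an (L, D) grid whose row ``i`` is the full z intensity
    profile at path pixel ``i``; the neurite shows as a dark band running
    left to right through it.
    """
    v = stack.voxels
    ys = np.array([p[0] for p in path.pixels])
    xs = np.array([p[1] for p in path.pixels])
    if ys.min() < 0 or xs.min() < 0 or ys.max() >= v.shape[1] or xs.max() >= v.shape[2]:
        raise IndexError("path leaves the stack bounds")
    return v[:, ys, xs].T.copy()


def depth_seam(z_img: np.ndarray, seam_max_step: int = 2) -> DepthSeam:
    """Minimal-intensity left-to-right seam through a z-image.

    Dynamic program over rows (path positions): the seam picks one z per
    position, moving at most ``seam_max_step`` planes between adjacent
    positions, minimizing the summed intensity.  Ties break toward
    smaller z.
    """
    z_img = np.asarray(z_img, dtype=np.float64)
    if z_img.size == 0:
        raise ValueError("empty z-image")
    L, D = z_img.shape
    cost = np.empty((L, D))
    back = np.zeros((L, D), dtype=np.int64)
    cost[0] = z_img[0]
    for i in range(1, L):
        for z in range(D):
            lo, hi = max(0, z - seam_max_step), min(D, z + seam_max_step + 1)
            window = cost[i - 1, lo:hi]
            j = int(np.argmin(window))  # argmin takes the first == smallest z
            back[i, z] = lo + j
            cost[i, z] = z_img[i, z] + window[j]
    z_end = int(np.argmin(cost[-1]))
    seam = np.empty(L, dtype=np.int64)
    seam[-1] = z_end
    for i in range(L - 1, 0, -1):
        seam[i - 1] = back[i, seam[i]]
    return DepthSeam(seam, float(cost[-1, z_end]))


def place_points(
    path: XYPath,
    dist_map: np.ndarray,
    seam: DepthSeam,
    spacing: tuple[float, float, float],
    rapid_dr_frac: float = 0.5,
    r_floor_um: float | None = None,
) -> list[TracePoint]:
    """Sample candidate points along a path.

    The gap between successive points is roughly the sum of their radii,
    halved where the radius changes rapidly (|dr| > ``rapid_dr_frac`` ×
    the smaller radius) so that sharp caliber changes are densely
    sampled.  The first and last path pixels are always sampled.
    """
    dx, dy, dz = spacing
    if r_floor_um is None:
        r_floor_um = 0.5 * dx
    ys = np.array([p[0] for p in path.pixels])
    xs = np.array([p[1] for p in path.pixels])
    radii = np.maximum(dist_map[ys, xs], r_floor_um)
    steps = np.hypot(np.diff(xs) * dx, np.diff(ys) * dy)
    arc = np.concatenate([[0.0], np.cumsum(steps)])

    def mk(i: int) -> TracePoint:
        return TracePoint(xs[i] * dx, ys[i] * dy, seam.z_index[i] * dz, float(radii[i]))

    chosen = [0]
    i = 1
    while i < len(path.pixels):
        j = chosen[-1]
        gap = radii[j] + radii[i]
        if abs(radii[i] - radii[j]) > rapid_dr_frac * min(radii[i], radii[j]):
            gap *= 0.5
        if arc[i] - arc[j] >= gap or i == len(path.pixels) - 1:
            chosen.append(i)
        i += 1
    if len(path.pixels) > 1 and chosen[-1] != len(path.pixels) - 1:
        chosen.append(len(path.pixels) - 1)
    return [mk(i) for i in chosen]


def refine_z(stack, point: TracePoint, z_window: int = 3, smooth_sigma: float = 2.0) -> float:
    """Snap a point's depth to the nearby minimum of the z intensity profile.

    The profile at the point's xy voxel is Gaussian-smoothed and the
    argmin within ±``z_window`` planes of the current z is taken; ties
    break toward the current plane.  Returns the new z in micrometres.
    """
    dx, dy, dz = stack.spacing
    ix = int(round(point.x / dx))
    iy = int(round(point.y / dy))
    iz = int(round(point.z / dz))
    Z, Y, X = stack.shape
    ix = min(max(ix, 0), X - 1)
    iy = min(max(iy, 0), Y - 1)
    iz = min(max(iz, 0), Z - 1)
    profile = gaussian_filter1d(stack.voxels[:, iy, ix], smooth_sigma, mode="nearest")
    lo, hi = max(0, iz - z_window), min(Z, iz + z_window + 1)
    window = profile[lo:hi]
    best = window.min()
    candidates = np.nonzero(window <= best + 1e-12)[0] + lo
    new_iz = int(candidates[np.argmin(np.abs(candidates - iz))])
    return new_iz * dz


def link_points(
    points: list[TracePoint],
    max_gap_um: float = 5.0,
    max_angle_deg: float = 100.0,
    max_dz_um: float = 5.0,
) -> list[int]:
    """Assign parents along an ordered point chain.

    Consecutive points are linked unless the gap exceeds ``max_gap_um``,
    the depth difference exceeds ``max_dz_um``, or linking would bend the
    chain at the shared point by more than ``max_angle_deg`` (sharp turns
    in neurites are biologically rare, so they flag tracing errors).
    The gap gate exists to catch distances created by point *removal*;
    since natural spacing is about the sum of the two radii, the
    effective threshold is ``max(max_gap_um, 1.5 * (r_a + r_b))`` so
    thick chains link at their natural spacing.  Returns a parent index
    per point (-1 where unlinked); the result is a set of simple
    chains, hence a forest.
    """
    parents = [-1] * len(points)
    for i in range(1, len(points)):
        p, q = points[i - 1], points[i]
        gap = float(np.linalg.norm(q.xyz - p.xyz))
        if gap > max(max_gap_um, 1.5 * (p.radius + q.radius)) or abs(q.z - p.z) > max_dz_um:
            continue
        if parents[i - 1] != -1:
            o = points[parents[i - 1]]
            v1 = p.xyz - o.xyz
            v2 = q.xyz - p.xyz
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 > 0 and n2 > 0:
                cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
                turn = np.degrees(np.arccos(cosang))
                if turn > max_angle_deg:
                    continue
        parents[i] = i - 1
    return parents
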