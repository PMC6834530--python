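"""Occupancy bookkeeping, 3D extension, soma recovery and reconnection.

The mask-derived trace misses faint stretches, crossings and thick
structures.  This module grows the trace in the full 3D stack:

* every linked point pair stamps a capsule (two half cylinders joined by
  a trapezoidal prism of linearly interpolated radius) into a boolean
  occupancy grid, so no stage re-traces explained volume;
* from each chain end an arc is swept ±60° about the outgoing direction
  and the intensity-weighted shortest path toward the arc's darkest
  reachable sample proposes the next candidate point, which must pass
  the (relaxed) validity test;
* if thick dendrites or the soma are darker than anything the trace
  covers, an intensity-threshold mask recovers them;
* remaining fragments are joined end-to-end by a greedy ascending-gap
  rule under distance, angle and depth gates, never forming a cycle.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.filters import threshold_otsu

from .centerline import (
    TracePoint,
    XYPath,
    depth_seam,
    distance_map,
    place_points,
    skeletonize_and_split,
    z_image,
)
from .swc import SWCTree
from .validity import ValidityParams, validate_and_adjust

__all__ = [
    "absorb_redundant",
    "OccupancyGrid",
    "GrowParams",
    "mark_occupied",
    "is_occupied",
    "weighted_shortest_path",
    "extend_from_end",
    "recover_thick",
    "connect_ends",
]


@dataclass
class OccupancyGrid:
    """Boolean voxel flags matching a stack, in the same index order."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    @classmethod
    def for_stack(cls, shape, spacing) -> "OccupancyGrid":
        return cls(np.zeros(shape, dtype=bool), tuple(spacing))


@dataclass
class GrowParams:
    """Extension and connection tunables (lengths in micrometres)."""

    arc_floor_um: float = 3.0      # arc radius is max(this, 2 * end radius)
    arc_span_deg: float = 60.0     # half-span about the outgoing direction
    arc_step_deg: float = 1.0
    dist_smooth_sigma: float = 3.0  # samples, on the arc distance profile
    seam_max_step: int = 2
    max_extend_points: int = 2000
    connect_max_gap_um: float = 5.0
    max_angle_deg: float = 100.0
    max_dz_um: float = 5.0
    soma_margin: float = 0.1
    soma_exclusion_um: float = 2.0
    validity: ValidityParams = field(default_factory=ValidityParams)


def _voxel_index(grid: OccupancyGrid, p: TracePoint | "object") -> tuple[int, int, int]:
    dx, dy, dz = grid.spacing
    Z, Y, X = grid.voxels.shape
    ix = min(max(int(round(p.x / dx)), 0), X - 1)
    iy = min(max(int(round(p.y / dy)), 0), Y - 1)
    iz = min(max(int(round(p.z / dz)), 0), Z - 1)
    return iz, iy, ix


def mark_occupied(grid: OccupancyGrid, p, q=None) -> OccupancyGrid:
    """Stamp the capsule between two connected points into the grid.

    Voxels whose centre lies within the linearly-interpolated-radius
    capsule around the segment p-q are set occupied; with ``q`` omitted
    (or equal to ``p``) a ball of radius ``p.radius`` is stamped.
    Re-marking is idempotent.
    """
    if q is None:
        q = p
    dx, dy, dz = grid.spacing
    Z, Y, X = grid.voxels.shape
    a = np.array([p.x, p.y, p.z])
    b = np.array([q.x, q.y, q.z])
    rmax = max(p.radius, q.radius)
    lo = np.minimum(a, b) - rmax
    hi = np.maximum(a, b) + rmax
    x0, x1 = max(int(np.floor(lo[0] / dx)), 0), min(int(np.ceil(hi[0] / dx)), X - 1)
    y0, y1 = max(int(np.floor(lo[1] / dy)), 0), min(int(np.ceil(hi[1] / dy)), Y - 1)
    z0, z1 = max(int(np.floor(lo[2] / dz)), 0), min(int(np.ceil(hi[2] / dz)), Z - 1)
    if x0 > x1 or y0 > y1 or z0 > z1:
        return grid
    zs, ys, xs = np.mgrid[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
    pts = np.stack([xs * dx, ys * dy, zs * dz], axis=-1).astype(float)
    d = b - a
    dd = float(d @ d)
    if dd == 0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - a) @ d) / dd, 0.0, 1.0)
    closest = a + t[..., None] * d
    radius = p.radius + t * (q.radius - p.radius)
    inside = np.linalg.norm(pts - closest, axis=-1) <= radius
    grid.voxels[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1] |= inside
    return grid


def is_occupied(grid: OccupancyGrid, p) -> bool:
    return bool(grid.voxels[_voxel_index(grid, p)])


@dataclass
class _PathResult:
    distances: dict[tuple[int, int], float]
    predecessors: dict[tuple[int, int], tuple[int, int] | None]

    def path_to(self, target: tuple[int, int]) -> list[tuple[int, int]]:
        path = [target]
        while self.predecessors[path[-1]] is not None:
            path.append(self.predecessors[path[-1]])
        return path[::-1]


def weighted_shortest_path(
    image2d: np.ndarray,
    src: tuple[int, int],
    target_set,
) -> tuple[dict[tuple[int, int], float], list[tuple[int, int]], "_PathResult"]:
    """Dijkstra on the 8-connected pixel grid with intensity-weighted steps.

    The cost of a step is the mean intensity of its two pixels times the
    Euclidean step length (in pixels), so dark channels are cheap and
    the minimal path follows the neurite.  Returns the per-target
    distances, the path to the cheapest target, and the full search
    result for further path extraction.
    """
    img = np.asarray(image2d, dtype=float)
    h, w = img.shape
    targets = {tuple(t) for t in target_set}
    if not (0 <= src[0] < h and 0 <= src[1] < w):
        raise IndexError("source out of bounds")
    for t in targets:
        if not (0 <= t[0] < h and 0 <= t[1] < w):
            raise IndexError(f"target {t} out of bounds")
    dist = {src: 0.0}
    pred: dict[tuple[int, int], tuple[int, int] | None] = {src: None}
    done: set[tuple[int, int]] = set()
    heap = [(0.0, src)]
    remaining = set(targets)
    while heap and remaining:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        remaining.discard(u)
        uy, ux = u
        for dy2 in (-1, 0, 1):
            for dx2 in (-1, 0, 1):
                if dy2 == 0 and dx2 == 0:
                    continue
                v = (uy + dy2, ux + dx2)
                if not (0 <= v[0] < h and 0 <= v[1] < w) or v in done:
                    continue
                step = 1.4142135623730951 if dy2 and dx2 else 1.0
                nd = d + 0.5 * (img[u] + img[v]) * step
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    pred[v] = u
                    heapq.heappush(heap, (nd, v))
    result = _PathResult(dist, pred)
    reach = {t: dist[t] for t in targets if t in dist}
    if not reach:
        return {}, [], result
    best = min(reach, key=lambda t: (reach[t], t))
    return reach, result.path_to(best), result


def _chain_direction(tree: SWCTree, end_id: int) -> np.ndarray | None:
    """Outgoing xy direction at a chain end (away from its neighbour).

    Walks several steps into the chain if the immediate neighbour sits
    at (numerically) the same xy position.
    """
    byid = tree.by_id()
    kids = tree.children()
    p = byid[end_id]
    prev = p.id
    cur = p.parent if p.parent != -1 else (kids[p.id][0] if kids[p.id] else -1)
    for _ in range(5):
        if cur == -1:
            return None
        q = byid[cur]
        d = np.array([p.x - q.x, p.y - q.y])
        n = np.linalg.norm(d)
        if n > 1e-9:
            return d / n
        nxt = q.parent if q.parent != prev and q.parent != -1 else -1
        if nxt == -1:
            others = [k for k in kids[q.id] if k != prev]
            nxt = others[0] if others else -1
        prev, cur = q.id, nxt
    return None


def extend_from_end(stack, tree: SWCTree, grid: OccupancyGrid, params: GrowParams | None = None) -> SWCTree:
    """Grow the trace in 3D from every chain end.

    For each end point: sweep an arc of radius max(``arc_floor_um``,
    2r) spanning ±``arc_span_deg`` about the outgoing direction in the
    end point's z-plane; Dijkstra the intensity-weighted distances from
    the end point to the arc samples; smooth the distance profile and
    follow the shortest path toward its minimum; recover depth along
    that path with the seam technique; accept the first candidate that
    passes the relaxed validity test, stamp its capsule and continue
    from it.  Extension from an end stops when a candidate lands on
    occupied volume (the fragments are joined later by
    :func:`connect_ends`) or when every candidate on the path fails.
    Isolated single points must already have been removed.
    """
    if params is None:
        params = GrowParams()
    dx, dy, dz = stack.spacing
    Z, Y, X = stack.shape
    ends = [p.id for p in tree.endpoints()]
    added = 0

    def connect_to_occupier(cur, cand) -> bool:
        """Join the end to the structure whose occupied volume stopped it."""
        comp_of = {}
        for ci, comp in enumerate(tree.components()):
            for i in comp:
                comp_of[i] = ci
        my_comp = comp_of[cur.id]
        best, best_d = None, np.inf
        for q in tree.points:
            if comp_of[q.id] == my_comp:
                continue
            d = float(np.linalg.norm(np.array([cand.x, cand.y, cand.z]) - q.xyz))
            if d < best_d:
                best, best_d = q, d
        if best is None or best_d > max(params.connect_max_gap_um, 2.0 * params.arc_floor_um):
            return False
        if abs(best.z - cur.z) > params.max_dz_um:
            return False
        tree.reroot(cur.id)
        tree.by_id()[cur.id].parent = best.id
        return True

    for end_id in ends:
        byid = tree.by_id()
        cur = byid[end_id]
        direction = _chain_direction(tree, end_id)
        if direction is None:
            continue
        while added < params.max_extend_points:
            arc_r_um = max(params.arc_floor_um, 2.0 * cur.radius)
            arc_r_px = arc_r_um / dx
            cy, cx = cur.y / dy, cur.x / dx
            iz = min(max(int(round(cur.z / dz)), 0), Z - 1)
            half = int(np.ceil(arc_r_px)) + 2
            y0, y1 = max(0, int(cy) - half), min(Y, int(cy) + half + 1)
            x0, x1 = max(0, int(cx) - half), min(X, int(cx) + half + 1)
            window = stack.voxels[iz, y0:y1, x0:x1]
            src = (
                min(max(int(round(cy)), y0), y1 - 1) - y0,
                min(max(int(round(cx)), x0), x1 - 1) - x0,
            )
            base = np.arctan2(direction[1], direction[0])
            span = np.deg2rad(params.arc_span_deg)
            angles = base + np.arange(-span, span + 1e-9, np.deg2rad(params.arc_step_deg))
            arc_px = []
            for t in angles:
                py = int(round(src[0] + arc_r_px * np.sin(t)))
                px = int(round(src[1] + arc_r_px * np.cos(t)))
                if 0 <= py < window.shape[0] and 0 <= px < window.shape[1]:
                    arc_px.append((py, px))
            if len(arc_px) < 3:
                break
            dists, _, search = weighted_shortest_path(window, src, arc_px)
            if not dists:
                break
            profile = np.array([dists.get(t, np.inf) for t in arc_px])
            finite = np.isfinite(profile)
            if not finite.any():
                break
            profile[~finite] = profile[finite].max()
            smoothed = gaussian_filter1d(profile, params.dist_smooth_sigma, mode="nearest")
            best_target = arc_px[int(np.argmin(smoothed))]
            path = search.path_to(best_target)
            if len(path) < 2:
                break
            gpath = XYPath([(py + y0, px + x0) for py, px in path])
            seam = depth_seam(z_image(stack, gpath), params.seam_max_step)
            steps = [0.0] + [
                np.hypot((path[i][1] - path[i - 1][1]) * dx, (path[i][0] - path[i - 1][0]) * dy)
                for i in range(1, len(path))
            ]
            arclen = np.cumsum(steps)
            accepted = None
            # skip candidates still inside the end point's own capsule,
            # where occupancy is trivially true
            min_arclen = 1.25 * cur.radius + 0.5 * dx
            for i in range(1, len(path)):
                if arclen[i] < min_arclen:
                    continue
                cand = TracePoint(
                    gpath.pixels[i][1] * dx,
                    gpath.pixels[i][0] * dy,
                    seam.z_index[i] * dz,
                    cur.radius,
                )
                if is_occupied(grid, cand):
                    connect_to_occupier(cur, cand)
                    accepted = None
                    break
                adj = validate_and_adjust(stack, cand, params.validity, stringency="relaxed")
                if adj is not None:
                    # the adjustment may have moved the point back onto
                    # already-explained volume
                    if is_occupied(grid, adj):
                        connect_to_occupier(cur, adj)
                        accepted = None
                        break
                    accepted = adj
                    break
            if accepted is None:
                break
            progress = np.hypot(accepted.x - cur.x, accepted.y - cur.y)
            if progress < max(0.5 * dx, 0.3 * cur.radius):
                break
            new = tree.add(3, accepted.x, accepted.y, accepted.z, accepted.radius, parent=cur.id)
            mark_occupied(grid, cur, new)
            direction_new = np.array([new.x - cur.x, new.y - cur.y])
            n = np.linalg.norm(direction_new)
            if n > 0:
                direction = direction_new / n
            cur = new
            added += 1
    return tree


def recover_thick(stack, projection, tree: SWCTree, params: GrowParams | None = None) -> list[list[TracePoint]]:
    """Recover soma and thick dendrites the valley mask missed.

    The valley detector is tuned to thin dendrites, so only the *edges*
    of a soma or thick trunk make it into the mask and their points die
    in the validity test.  Thick structures are the darkest part of the
    projection; if the darkest covered pixel (robust 1st percentile over
    the footprints of existing points) is brighter than the darkest
    pixel overall by more than ``soma_margin``, an Otsu intensity
    threshold on the projection — excluding a zone around existing
    points — yields a recovery mask, which is skeletonized, placed and
    validated like any other, with soma-scale radii allowed.  Returns
    one chain of validated points per recovered skeleton path, ready to
    be linked in order.
    """
    if params is None:
        params = GrowParams()
    dx, dy, dz = stack.spacing
    pix = projection.pixels
    H, W = pix.shape
    covered = np.zeros((H, W), dtype=bool)
    for p in tree.points:
        r_px = max(int(np.ceil(p.radius / dx)), 1)
        cy, cx = int(round(p.y / dy)), int(round(p.x / dx))
        y0, y1 = max(0, cy - r_px), min(H, cy + r_px + 1)
        x0, x1 = max(0, cx - r_px), min(W, cx + r_px + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        covered[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    global_min = float(np.quantile(pix, 0.01))
    covered_min = float(np.quantile(pix[covered], 0.01)) if covered.any() else np.inf
    if covered_min <= global_min + params.soma_margin:
        return []
    excl_px = max(int(np.ceil(params.soma_exclusion_um / dx)), 1)
    from scipy.ndimage import binary_dilation

    excluded = binary_dilation(covered, iterations=excl_px) if covered.any() else covered
    candidates_pix = pix[~excluded]
    if candidates_pix.size < 16 or candidates_pix.max() == candidates_pix.min():
        return []
    thr = threshold_otsu(candidates_pix)
    # floor the threshold so a mostly-background histogram cannot push it high
    thr = min(thr, global_min + 0.5 * (float(np.median(pix)) - global_min))
    mask = (pix < thr) & ~excluded
    if not mask.any():
        return []
    dmap = distance_map(mask, (dx, dy))
    soma_validity = ValidityParams(
        sigma=params.validity.sigma,
        r_min_um=params.validity.r_min_um,
        r_max_um=params.validity.r_max_um,
        n_iter=params.validity.n_iter,
    )
    out: list[list[TracePoint]] = []
    for path in skeletonize_and_split(mask):
        seam = depth_seam(z_image(stack, path), params.seam_max_step)
        chain = []
        for cand in place_points(path, dmap, seam, stack.spacing):
            adj = validate_and_adjust(stack, cand, soma_validity, stringency="standard")
            if adj is not None:
                chain.append(adj)
        if chain:
            out.append(chain)
    return out


def absorb_redundant(tree: SWCTree, ratio: float = 1.25, thick_min_um: float = 2.0) -> SWCTree:
    """Drop points whose centre lies inside a thick structure's ball.

    The occupancy rule applied retrospectively, restricted to soma-scale
    absorbers (radius >= ``thick_min_um``): the valley mask traces a
    ring of small spurious points around a soma, and several soma-scale
    detections of one soma can coexist.  A point centred inside a thick
    ball of radius >= ``ratio`` times its own — or deeply overlapping a
    thick near-equal — is redundant.  Children of an absorbed point
    re-parent to the absorbing point unless that would create a cycle.
    Thin-dendrite chains are never touched.
    """
    order = sorted(tree.points, key=lambda p: (-p.radius, p.id))
    kept: list = []
    drop: dict[int, int] = {}  # absorbed id -> absorber id
    for p in order:
        absorber = None
        for t in kept:
            if t.radius < thick_min_um:
                continue
            d = float(np.linalg.norm(p.xyz - t.xyz))
            clearly_larger = t.radius >= ratio * p.radius and d <= t.radius
            # two soma-scale detections of one thick structure
            both_thick = p.radius >= thick_min_um and d <= t.radius
            # near-equal radius but centres much closer than either ball
            deep_overlap = d <= t.radius - 0.5 * p.radius
            if clearly_larger or both_thick or deep_overlap:
                absorber = t
                break
        if absorber is None:
            kept.append(p)
        else:
            drop[p.id] = absorber.id
    if not drop:
        return tree
    byid = tree.by_id()

    def ancestors(i: int):
        seen = set()
        while i != -1 and i in byid and i not in seen:
            seen.add(i)
            yield i
            i = byid[i].parent

    for p in tree.points:
        if p.id in drop:
            continue
        while p.parent in drop:
            p.parent = drop[p.parent]
        if p.parent != -1 and p.id in set(ancestors(p.parent)):
            p.parent = -1
    tree.points = [p for p in tree.points if p.id not in drop]
    return tree


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def connect_ends(tree: SWCTree, params: GrowParams | None = None) -> SWCTree:
    """Join broken fragments end-to-end with greedy distance heuristics.

    Candidate pairs are chain ends from different components whose gap
    is at most ``connect_max_gap_um``; they must also pass the depth gate
    (|dz| <= ``max_dz_um``) and the turning-angle gate at both ends.
    Pairs are connected in ascending-gap order, mutual-nearest pairs
    first, with a union-find guard so no cycle can form.  When the gap
    exceeds the sum of the end radii, evenly spaced points are
    interpolated across it.
    """
    if params is None:
        params = GrowParams()
    if len(tree) == 0:
        return tree
    comps = tree.components()
    comp_of = {}
    for ci, comp in enumerate(comps):
        for i in comp:
            comp_of[i] = ci
    byid = tree.by_id()
    ends = tree.endpoints()

    def angle_ok(end, other) -> bool:
        # a soma-scale point has no meaningful outgoing direction;
        # branches leave a soma at any angle
        if end.radius >= 2.0:
            return True
        d = _chain_direction(tree, end.id)
        if d is None:
            return True
        v = np.array([other.x - end.x, other.y - end.y])
        n = np.linalg.norm(v)
        if n == 0:
            return True
        cosang = np.clip(float(d @ (v / n)), -1.0, 1.0)
        return np.degrees(np.arccos(cosang)) <= params.max_angle_deg

    pairs = []
    for i, a in enumerate(ends):
        for b in ends[i + 1 :]:
            if comp_of[a.id] == comp_of[b.id]:
                continue
            gap = float(np.linalg.norm(a.xyz - b.xyz))
            reach = max(params.connect_max_gap_um, 1.5 * (a.radius + b.radius))
            if gap > reach or abs(a.z - b.z) > params.max_dz_um:
                continue
            if not (angle_ok(a, b) and angle_ok(b, a)):
                continue
            pairs.append((gap, a.id, b.id))
    # mutual-nearest pairs first, then ascending gap
    nearest: dict[int, tuple[float, int]] = {}
    for gap, ai, bi in pairs:
        for s, t in ((ai, bi), (bi, ai)):
            if s not in nearest or gap < nearest[s][0]:
                nearest[s] = (gap, t)
    def mutual(gap, ai, bi):
        return nearest.get(ai, (None, None))[1] == bi and nearest.get(bi, (None, None))[1] == ai
    pairs.sort(key=lambda p: (not mutual(*p), p[0], p[1], p[2]))

    uf = _UnionFind(range(len(comps)))
    for gap, ai, bi in pairs:
        if not uf.union(comp_of[ai], comp_of[bi]):
            continue
        a, b = byid[ai], byid[bi]
        tree.reroot(bi)
        if gap > a.radius + b.radius:
            n_mid = int(np.floor(gap / (a.radius + b.radius)))
            prev = a
            for k in range(1, n_mid + 1):
                t = k / (n_mid + 1)
                mid = tree.add(
                    3,
                    a.x + t * (b.x - a.x),
                    a.y + t * (b.y - a.y),
                    a.z + t * (b.z - a.z),
                    a.radius + t * (b.radius - a.radius),
                    parent=prev.id,
                )
                comp_of[mid.id] = uf.find(comp_of[ai])
                prev = mid
            byid = tree.by_id()
            byid[bi].parent = prev.id
        else:
            byid[bi].parent = ai
    return tree
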