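"""Evaluation of a traced morphology against ground truth.

Used with the synthetic renderer, where the generating tree is known
exactly.  Recall is measured along cable: the ground-truth tree is
sampled densely along its edges and a sample counts as recovered when
it lies within a tolerance of the traced *polyline* (points plus the
straight edges between linked points — an SWC file represents cable,
not isolated dots).
"""

from __future__ import annotations

import numpy as np

from .swc import SWCTree

__all__ = ["sample_cable", "distance_to_polyline", "centerline_recall", "radius_errors", "terminal_tips"]


def sample_cable(tree: SWCTree, step_um: float = 0.2) -> np.ndarray:
    """Sample points densely along every edge of a tree.

    Returns an (N, 4) array of x, y, z and the interpolated radius.
    """
    byid = tree.by_id()
    samples = []
    for p in tree.points:
        if p.parent == -1:
            continue
        q = byid[p.parent]
        length = float(np.linalg.norm(p.xyz - q.xyz))
        n = max(int(length / step_um), 1)
        for t in np.linspace(0.0, 1.0, n + 1):
            pos = q.xyz + t * (p.xyz - q.xyz)
            samples.append([pos[0], pos[1], pos[2], q.radius + t * (p.radius - q.radius)])
    if not samples:
        return np.empty((0, 4))
    return np.asarray(samples)


def distance_to_polyline(points: np.ndarray, tree: SWCTree) -> np.ndarray:
    """Distance from each query point to the nearest traced edge (or point)."""
    points = np.atleast_2d(points)
    byid = tree.by_id()
    segs = []
    for p in tree.points:
        if p.parent != -1:
            segs.append((byid[p.parent].xyz, p.xyz))
        else:
            segs.append((p.xyz, p.xyz))
    if not segs:
        return np.full(len(points), np.inf)
    a = np.array([s[0] for s in segs])  # (S, 3)
    b = np.array([s[1] for s in segs])
    d = b - a
    dd = (d * d).sum(1)
    dd[dd == 0] = 1.0
    ap = points[:, None, :] - a[None, :, :]          # (N, S, 3)
    t = np.clip((ap * d[None]).sum(-1) / dd[None], 0.0, 1.0)
    closest = a[None] + t[..., None] * d[None]
    dist = np.linalg.norm(points[:, None, :] - closest, axis=-1)
    return dist.min(axis=1)


def centerline_recall(truth: SWCTree, traced: SWCTree, tol_um: float = 1.0) -> float:
    """Fraction of ground-truth cable explained by the traced polyline.

    A cable sample counts as recovered when the traced polyline passes
    within ``max(tol_um, local radius)`` of it: a trace running inside
    the tube explains that stretch of cable even if it is slightly off
    the geometric axis (depth inside a thick structure is genuinely
    ambiguous in transmitted light).
    """
    samples = sample_cable(truth)
    if samples.size == 0:
        return 1.0 if len(traced) >= 0 else 0.0
    if len(traced) == 0:
        return 0.0
    tol = np.maximum(tol_um, samples[:, 3])
    return float((distance_to_polyline(samples[:, :3], traced) <= tol).mean())


def radius_errors(truth: SWCTree, traced: SWCTree, match_tol_um: float = 1.5) -> np.ndarray:
    """Relative radius error of each traced point matched to ground truth.

    Each traced point is matched to the nearest ground-truth point
    within ``match_tol_um``; unmatched points are skipped.
    """
    if len(truth) == 0 or len(traced) == 0:
        return np.empty(0)
    gt = np.array([[p.x, p.y, p.z, p.radius] for p in truth.points])
    errs = []
    for p in traced.points:
        d = np.linalg.norm(gt[:, :3] - p.xyz, axis=1)
        j = int(np.argmin(d))
        if d[j] <= match_tol_um and gt[j, 3] > 0:
            errs.append(abs(p.radius - gt[j, 3]) / gt[j, 3])
    return np.asarray(errs)


def terminal_tips(tree: SWCTree) -> int:
    """Number of degree-1 leaves excluding the root/soma point."""
    deg = tree.degree()
    return sum(1 for p in tree.points if deg[p.id] == 1 and p.parent != -1)
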