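"""Ground-truth synthesis: trees, bright-field-like stacks, tiled scenes.

The renderer emulates what makes stained-neuron bright-field stacks hard
to trace: dark tubular neurites on a bright (~1.0) background, additive
sensor noise, dark blob artifacts (dye spills, dirt), fixation "beading"
that fragments thin branches into spheres with faint gaps, and a
z-elongated point-spread function that casts out-of-focus shadows above
and below each branch.  It is a geometric absorption model, not physical
optics — sufficient to exercise every branch of the tracing pipeline
with exact ground truth attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .stacks import GrayStack
from .stitch import TileLayout
from .swc import SWCTree

__all__ = ["TreeSpec", "RenderParams", "TileSet", "make_tree", "render_stack", "make_tiles"]


@dataclass
class TreeSpec:
    """Geometry of a synthetic dendritic tree.

    A trunk of ``segment_length_um`` starts at ``root`` heading along
    ``direction``; at each of ``levels`` bifurcation levels the branch
    splits in two at ±``branch_angle_deg``/2 (kept < 90° total — sharp
    turns are rare in real neurites).  A balanced tree of L levels has
    2^L terminal tips and 2^L - 1 bifurcation points.  Radii taper by
    ``radius_taper`` per level.
    """

    root: tuple[float, float, float] = (2.0, 12.0, 8.0)
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    segment_length_um: float = 10.0
    points_per_segment: int = 5
    levels: int = 0
    radius_um: float = 1.0
    radius_taper: float = 0.75
    branch_angle_deg: float = 50.0
    angle_jitter_deg: float = 5.0
    z_wobble_um: float = 0.0
    soma_radius_um: float = 0.0  # > 0 renders a soma bulb at the root


@dataclass
class RenderParams:
    """Appearance of the rendered bright-field stack.

    Intensities in [0, 1]; tube centres sit at
    ``background_level - neurite_contrast``.  ``psf_z_um`` is elongated
    relative to ``psf_xy_um`` (default 4×) to produce the out-of-focus
    z shadows characteristic of transmitted-light stacks.  ``seed``
    makes the rendering bit-exact reproducible.
    """

    background_level: float = 0.95
    neurite_contrast: float = 0.5
    noise_sd: float = 0.0
    psf_xy_um: float = 0.15
    psf_z_um: float = 0.6
    bead_fraction: float = 0.0
    bead_gap_um: float = 2.0
    bead_max_radius_um: float = 0.5
    bead_swell: float = 1.6  # beads are swellings, wider than the neurite
    bead_gap_contrast_frac: float = 0.08
    blob_count: int = 0
    blob_radius_um: float = 2.0
    seed: int = 0


@dataclass
class TileSet:
    """Tiles cropped from one scene plus the ground-truth layout."""

    tiles: dict[int, GrayStack]
    layout: TileLayout
    true_offsets: dict[tuple[int, int], tuple[int, int, int]]
    text: str


def _rotate_xy(v: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


def make_tree(spec: TreeSpec, seed: int = 0) -> SWCTree:
    """Grow a deterministic synthetic tree from a :class:`TreeSpec`."""
    if spec.levels < 0 or spec.points_per_segment < 1 or spec.segment_length_um <= 0:
        raise ValueError("infeasible tree spec")
    if spec.branch_angle_deg + spec.angle_jitter_deg >= 90.0:
        raise ValueError("total branch angle must stay below 90 degrees")
    rng = np.random.default_rng(seed)
    tree = SWCTree()
    d0 = np.asarray(spec.direction, dtype=float)
    d0 = d0 / np.linalg.norm(d0)

    def grow(start: np.ndarray, direction: np.ndarray, level: int, radius: float, parent_id: int):
        step = spec.segment_length_um / spec.points_per_segment
        pos = start.copy()
        pid = parent_id
        for _ in range(spec.points_per_segment):
            pos = pos + direction * step
            if spec.z_wobble_um > 0:
                pos[2] += rng.normal(0.0, spec.z_wobble_um * step / spec.segment_length_um)
            p = tree.add(3, pos[0], pos[1], pos[2], radius, parent=pid)
            pid = p.id
        if level < spec.levels:
            half = np.deg2rad(spec.branch_angle_deg / 2.0)
            for sign in (+1, -1):
                jit = np.deg2rad(rng.uniform(-spec.angle_jitter_deg, spec.angle_jitter_deg))
                child_dir = _rotate_xy(direction, sign * half + jit)
                grow(pos, child_dir, level + 1, radius * spec.radius_taper, pid)

    root = np.asarray(spec.root, dtype=float)
    if spec.soma_radius_um > 0:
        first = tree.add(1, root[0], root[1], root[2], spec.soma_radius_um, parent=-1)
    else:
        first = tree.add(3, root[0], root[1], root[2], spec.radius_um, parent=-1)
    grow(root, d0, 0, spec.radius_um, first.id)
    tree.validate()
    return tree


def _paint_capsule(darkness, a, b, ra, rb, level, spacing, aa_px=1.0):
    """Darken voxels inside the capsule a-b (linear radius), antialiased."""
    dx, dy, dz = spacing
    Z, Y, X = darkness.shape
    rmax = max(ra, rb) + aa_px * dx
    lo = np.minimum(a, b) - rmax
    hi = np.maximum(a, b) + rmax
    x0, x1 = max(int(np.floor(lo[0] / dx)), 0), min(int(np.ceil(hi[0] / dx)), X - 1)
    y0, y1 = max(int(np.floor(lo[1] / dy)), 0), min(int(np.ceil(hi[1] / dy)), Y - 1)
    z0, z1 = max(int(np.floor(lo[2] / dz)), 0), min(int(np.ceil(hi[2] / dz)), Z - 1)
    if x0 > x1 or y0 > y1 or z0 > z1:
        return
    zs, ys, xs = np.mgrid[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
    pts = np.stack([xs * dx, ys * dy, zs * dz], axis=-1).astype(float)
    d = b - a
    dd = float(d @ d)
    t = np.zeros(pts.shape[:-1]) if dd == 0 else np.clip(((pts - a) @ d) / dd, 0.0, 1.0)
    closest = a + t[..., None] * d
    radius = ra + t * (rb - ra)
    dist = np.linalg.norm(pts - closest, axis=-1)
    frac = np.clip((radius + 0.5 * aa_px * dx - dist) / (aa_px * dx), 0.0, 1.0)
    region = darkness[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
    np.maximum(region, level * frac, out=region)


def render_stack(
    tree: SWCTree,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    params: RenderParams | None = None,
) -> tuple[GrayStack, dict]:
    """Render a tree into a bright-field-like stack with ground truth.

    Returns the stack and a ground-truth dict with the source ``tree``
    and a boolean ``centerline`` volume (voxels within half a voxel of
    the analytic tube axis).
    """
    if params is None:
        params = RenderParams()
    rng = np.random.default_rng(params.seed)
    dx, dy, dz = spacing
    darkness = np.zeros(shape, dtype=np.float64)
    centerline = np.zeros(shape, dtype=bool)
    byid = tree.by_id()
    contrast = params.neurite_contrast

    for p in tree.points:
        if p.parent == -1:
            continue
        q = byid[p.parent]
        a, b = q.xyz, p.xyz
        beaded = (
            params.bead_fraction > 0
            and min(p.radius, q.radius) <= params.bead_max_radius_um
            and rng.random() < params.bead_fraction
        )
        if beaded:
            # faint continuous tube plus dark beads separated by gaps
            _paint_capsule(darkness, a, b, q.radius, p.radius,
                           params.bead_gap_contrast_frac * contrast, spacing)
            seg_len = float(np.linalg.norm(b - a))
            period = 2.0 * p.radius * params.bead_swell + params.bead_gap_um
            n_beads = max(int(seg_len / period) + 1, 1)
            for k in range(n_beads):
                t = min(k * period / seg_len, 1.0) if seg_len > 0 else 0.0
                c = a + t * (b - a)
                r = (q.radius + t * (p.radius - q.radius)) * params.bead_swell
                _paint_capsule(darkness, c, c, r, r, contrast, spacing)
        else:
            _paint_capsule(darkness, a, b, q.radius, p.radius, contrast, spacing)
        # ground-truth centerline: nearest voxel along the axis
        seg_len = float(np.linalg.norm(b - a))
        n_s = max(int(seg_len / (0.25 * min(dx, dy, dz))), 1)
        for t in np.linspace(0.0, 1.0, n_s + 1):
            c = a + t * (b - a)
            iz = int(round(c[2] / dz))
            iy = int(round(c[1] / dy))
            ix = int(round(c[0] / dx))
            if 0 <= iz < shape[0] and 0 <= iy < shape[1] and 0 <= ix < shape[2]:
                centerline[iz, iy, ix] = True

    for _ in range(params.blob_count):
        c = np.array([
            rng.uniform(0, (shape[2] - 1) * dx),
            rng.uniform(0, (shape[1] - 1) * dy),
            rng.uniform(0, (shape[0] - 1) * dz),
        ])
        _paint_capsule(darkness, c, c, params.blob_radius_um, params.blob_radius_um,
                       contrast, spacing)

    img = params.background_level - darkness
    if params.psf_xy_um > 0 or params.psf_z_um > 0:
        img = gaussian_filter(
            img, (params.psf_z_um / dz, params.psf_xy_um / dy, params.psf_xy_um / dx),
            mode="nearest",
        )
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    stack = GrayStack(img, spacing)
    return stack, {"tree": tree, "centerline": centerline}


def make_tiles(
    stack: GrayStack,
    n_cols: int,
    n_rows: int,
    overlap_pct: float = 20.0,
    jitter_px: int = 0,
    seed: int = 0,
) -> TileSet:
    """Crop a scene into an overlapping tile grid with known offsets.

    Nominal offsets follow the layout grammar (shift =
    ``100 - overlap_pct`` percent of the tile size); the true offsets
    add integer jitter of at most ``jitter_px`` pixels per pair, which
    the stitcher must recover exactly.  Also emits the matching layout
    file text.  Tiles are numbered row-major from 1.
    """
    rng = np.random.default_rng(seed)
    Z, Y, X = stack.shape
    s = (100.0 - overlap_pct) / 100.0
    tile_w = int(X / (1 + (n_cols - 1) * s)) if n_cols > 1 else X
    tile_h = int(Y / (1 + (n_rows - 1) * s)) if n_rows > 1 else Y
    shift_x = int(round(s * tile_w))
    shift_y = int(round(s * tile_h))
    max_x = (n_cols - 1) * shift_x + tile_w
    max_y = (n_rows - 1) * shift_y + tile_h
    if max_x > X or max_y > Y or tile_w < 4 or tile_h < 4:
        raise ValueError("tiles would not cover the stack at this grid/overlap")

    # true per-tile origins: nominal grid plus clamped integer jitter
    origins: dict[int, tuple[int, int]] = {}
    tid = 1
    for r in range(n_rows):
        for c in range(n_cols):
            jx = int(rng.integers(-jitter_px, jitter_px + 1)) if jitter_px else 0
            jy = int(rng.integers(-jitter_px, jitter_px + 1)) if jitter_px else 0
            ox = min(max(c * shift_x + jx, 0), X - tile_w)
            oy = min(max(r * shift_y + jy, 0), Y - tile_h)
            if (r, c) == (0, 0):
                ox, oy = 0, 0
            origins[tid] = (ox, oy)
            tid += 1

    tiles = {
        t: GrayStack(
            stack.voxels[:, oy : oy + tile_h, ox : ox + tile_w].copy(),
            stack.spacing,
            origin_tile=str(t),
        )
        for t, (ox, oy) in origins.items()
    }
    rows = [[r * n_cols + c + 1 for c in range(n_cols)] for r in range(n_rows)]
    links = [(rows[r][0], rows[r + 1][0]) for r in range(n_rows - 1)]
    layout = TileLayout([t for row in rows for t in row], rows, links, 100.0 - overlap_pct)
    true_offsets: dict[tuple[int, int], tuple[int, int, int]] = {}
    for pair in layout.adjacent_pairs():
        a, b = pair
        true_offsets[pair] = (
            origins[b][0] - origins[a][0],
            origins[b][1] - origins[a][1],
            0,
        )
    lines = [f"{layout.overlap_pct:g}"]
    for i, row in enumerate(rows):
        lines.append(", ".join(str(t) for t in row))
        if i < len(links):
            lines.append(f"{links[i][0]}, {links[i][1]}")
    text = "\n".join(lines) + "\n"
    return TileSet(tiles, layout, true_offsets, text)
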