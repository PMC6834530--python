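"""Tile stitching and whole-neuron SWC assembly.

A neuron larger than one field of view is imaged as overlapping tiles.
The tile layout file gives the scan order and the nominal shift; the
precise integer offsets between adjacent tiles are recovered by
maximizing normalized phase correlation on minimum-intensity
projections of the overlap regions.  A maximum spanning tree over the
pairwise correlation weights picks the most reliable offsets to resolve
global tile coordinates.  Per-tile traces are then translated, merged
with occupancy deduplication in the overlap bands, reconnected across
tile seams, and pruned of short isolated branches and small protrusions.

Layout file grammar (one example)::

    80
    1, 2, 3, 4
    1, 5
    5, 6, 7, 8
    6, 9
    9

The first line is the shift between adjacent tiles as a percentage of
the tile size (80 means ~20% overlap).  Row lines (tiles scanned left to
right) alternate with link lines naming one connected tile pair between
consecutive rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .grow import GrowParams, OccupancyGrid, connect_ends, is_occupied, mark_occupied
from .stacks import GrayStack, min_projection
from .swc import SWCPoint, SWCTree, read_swc, write_swc  # noqa: F401  (re-exported)

__all__ = [
    "TileLayout",
    "parse_layout",
    "layout_to_text",
    "nominal_pair_offsets",
    "pair_offset",
    "spanning_layout",
    "combine_and_prune",
    "prune_tree",
    "read_swc",
    "write_swc",
]


@dataclass
class TileLayout:
    """Tiles, their scan rows, pairwise offsets and resolved coordinates.

    ``overlap_pct`` stores the layout file's first line: the shift
    between adjacent tiles as a percentage of the tile size (100 means
    edge-to-edge; 80 means 20% overlap).  ``pair_offsets`` maps an
    adjacent tile pair (a, b) to ``((dx, dy, dz), weight)``: the offset
    of b's origin relative to a's in pixels, with the phase-correlation
    peak as weight.  ``global_xy`` holds resolved per-tile coordinates
    in pixels.
    """

    tiles: list[int]
    rows: list[list[int]]
    row_links: list[tuple[int, int]]
    overlap_pct: float
    pair_offsets: dict[tuple[int, int], tuple[tuple[int, int, int], float]] = field(default_factory=dict)
    global_xy: dict[int, tuple[float, float]] = field(default_factory=dict)

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        pairs = []
        for row in self.rows:
            pairs.extend(zip(row, row[1:]))
        pairs.extend(self.row_links)
        return pairs


def parse_layout(text: str) -> TileLayout:
    """Parse a tile-layout file into a :class:`TileLayout`."""
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(text.splitlines())]
    lines = [(n, ln) for n, ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError("empty layout file")
    n0, first = lines[0]
    try:
        overlap_pct = float(first)
    except ValueError as exc:
        raise ValueError(f"line {n0}: expected the shift percentage, got {first!r}") from exc

    def ints(n, ln):
        try:
            return [int(tok) for tok in ln.replace(",", " ").split()]
        except ValueError as exc:
            raise ValueError(f"line {n}: malformed tile list {ln!r}") from exc

    rows: list[list[int]] = []
    links: list[tuple[int, int]] = []
    for k, (n, ln) in enumerate(lines[1:]):
        vals = ints(n, ln)
        if k % 2 == 0:  # row line
            if not vals:
                raise ValueError(f"line {n}: empty row")
            rows.append(vals)
        else:  # link line
            if len(vals) != 2:
                raise ValueError(f"line {n}: a row link needs exactly two tiles, got {vals}")
            links.append((vals[0], vals[1]))
    tiles = [t for row in rows for t in row]
    if len(tiles) != len(set(tiles)):
        raise ValueError("duplicate tile id in rows")
    tileset = set(tiles)
    for a, b in links:
        if a not in tileset or b not in tileset:
            raise ValueError(f"row link ({a}, {b}) names a tile absent from the rows")
    return TileLayout(tiles, rows, links, overlap_pct)


def layout_to_text(layout: TileLayout) -> str:
    """Serialize a layout back to the tile-sequences grammar."""
    lines = [f"{layout.overlap_pct:g}"]
    for i, row in enumerate(layout.rows):
        lines.append(", ".join(str(t) for t in row))
        if i < len(layout.row_links):
            a, b = layout.row_links[i]
            lines.append(f"{a}, {b}")
    return "\n".join(lines) + "\n"


def nominal_pair_offsets(layout: TileLayout, tile_shape: tuple[int, int]) -> dict[tuple[int, int], tuple[int, int, int]]:
    """Nominal (dx, dy, dz) pixel offsets for every adjacent pair.

    Within a row the right-hand tile sits ``overlap_pct``% of the tile
    width to the right; a row link puts the lower tile the same fraction
    of the height down.
    """
    H, W = tile_shape
    shift_x = int(round(layout.overlap_pct / 100.0 * W))
    shift_y = int(round(layout.overlap_pct / 100.0 * H))
    out = {}
    for row in layout.rows:
        for a, b in zip(row, row[1:]):
            out[(a, b)] = (shift_x, 0, 0)
    for a, b in layout.row_links:
        out[(a, b)] = (0, shift_y, 0)
    return out


def _phase_corr_residual(a: np.ndarray, b: np.ndarray, margin: int) -> tuple[tuple[int, int], float]:
    """Integer shift of b relative to a (b[y,x] ~ a[y+sy, x+sx]) within ±margin."""
    a = a - a.mean()
    b = b - b.mean()
    FA = np.fft.fft2(a)
    FB = np.fft.fft2(b)
    cross = FA * np.conj(FB)
    mag = np.abs(cross)
    if not np.any(mag > 1e-12):
        return (0, 0), 0.0
    r = np.fft.ifft2(cross / np.maximum(mag, 1e-12)).real
    H, W = r.shape
    best, best_val = (0, 0), -np.inf
    for sy in range(-margin, margin + 1):
        for sx in range(-margin, margin + 1):
            val = r[sy % H, sx % W]
            if val > best_val:
                best, best_val = (sy, sx), val
    return best, float(np.clip(best_val, 0.0, 1.0))


def pair_offset(
    stack_a: GrayStack,
    stack_b: GrayStack,
    nominal: tuple[int, int, int],
    search_margin: int = 10,
) -> tuple[tuple[int, int, int], float]:
    """Refine the offset of tile B relative to tile A by phase correlation.

    Minimum-intensity projections of the two tiles are cropped to the
    overlap under the nominal offset and phase-correlated; the residual
    peak within ±``search_margin`` pixels corrects the nominal.  The z
    component is kept nominal (tiles are imaged laterally in one
    session).  The returned weight is the correlation peak in [0, 1];
    a degenerate (constant) overlap yields the nominal with weight 0.
    """
    pa = min_projection(stack_a).pixels
    pb = min_projection(stack_b).pixels
    ox, oy, oz = nominal
    H, W = pa.shape
    y0, y1 = max(oy, 0), H + min(oy, 0)
    x0, x1 = max(ox, 0), W + min(ox, 0)
    if y1 - y0 <= 2 * search_margin or x1 - x0 <= 2 * search_margin:
        return (ox, oy, oz), 0.0
    crop_a = pa[y0:y1, x0:x1]
    crop_b = pb[y0 - oy : y1 - oy, x0 - ox : x1 - ox]
    if crop_a.max() == crop_a.min() or crop_b.max() == crop_b.min():
        return (ox, oy, oz), 0.0
    (sy, sx), weight = _phase_corr_residual(crop_a, crop_b, search_margin)
    return (ox + sx, oy + sy, oz), weight


def spanning_layout(layout: TileLayout) -> TileLayout:
    """Resolve global tile coordinates over a maximum spanning tree.

    Edges are the refined pairwise offsets weighted by their phase
    correlation; the spanning tree keeps the most reliable offsets and
    discards inconsistent low-weight ones.  Coordinates accumulate from
    the lowest tile id (placed at (0, 0)) along tree edges; ties between
    equal-weight edges break by (a, b) lexical order.
    """
    g = nx.Graph()
    g.add_nodes_from(layout.tiles)
    for (a, b), (off, w) in layout.pair_offsets.items():
        g.add_edge(a, b, weight=w, offset=off, pair=(a, b))
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(f"tile graph is disconnected: components {comps}")
    edges = sorted(g.edges(data=True), key=lambda e: (-e[2]["weight"], e[0], e[1]))
    uf_parent = {t: t for t in layout.tiles}

    def find(t):
        while uf_parent[t] != t:
            uf_parent[t] = uf_parent[uf_parent[t]]
            t = uf_parent[t]
        return t

    tree_adj: dict[int, list[tuple[int, tuple[int, int, int], int]]] = {t: [] for t in layout.tiles}
    for a, b, data in edges:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        uf_parent[rb] = ra
        pa, pb_ = data["pair"]
        off = data["offset"]
        tree_adj[pa].append((pb_, off, +1))
        tree_adj[pb_].append((pa, off, -1))
    root = min(layout.tiles)
    global_xy = {root: (0.0, 0.0)}
    stack = [root]
    while stack:
        t = stack.pop()
        gx, gy = global_xy[t]
        for other, (dx, dy, _dz), sign in tree_adj[t]:
            if other in global_xy:
                continue
            global_xy[other] = (gx + sign * dx, gy + sign * dy)
            stack.append(other)
    layout.global_xy = global_xy
    return layout


def prune_tree(
    tree: SWCTree,
    min_component_um: float = 20.0,
    min_twig_points: int = 5,
    keep_radius_um: float = 2.0,
) -> SWCTree:
    """Delete noise branches: short isolated components and small twigs.

    Connected components of total cable length below
    ``min_component_um`` are removed, as are side twigs of fewer than
    ``min_twig_points`` points hanging off a branch point.  Noise is
    thin: anything containing a soma-scale point (radius >=
    ``keep_radius_um``) is exempt.  Both rules iterate to a fixed
    point, which makes pruning idempotent.
    """
    changed = True
    while changed:
        changed = False
        byid = tree.by_id()
        # short isolated components
        drop: set[int] = set()
        for comp in tree.components():
            if tree.cable_length(comp) < min_component_um and not any(
                byid[i].radius >= keep_radius_um for i in comp
            ):
                drop.update(comp)
        # small protrusions: tip-terminated chains shorter than the
        # point threshold, attached at a branch point
        deg = tree.degree()
        kids = tree.children()
        for p in tree.points:
            if p.id in drop or deg[p.id] != 1:
                continue
            chain = [p.id]
            cur = p
            while True:
                nbrs = ([cur.parent] if cur.parent != -1 else []) + kids[cur.id]
                nbrs = [n for n in nbrs if n not in chain]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                if deg[nxt] >= 3:
                    if len(chain) < min_twig_points and not any(
                        byid[i].radius >= keep_radius_um for i in chain
                    ):
                        drop.update(chain)
                    break
                chain.append(nxt)
                cur = byid[nxt]
                if len(chain) >= min_twig_points:
                    break
        if drop:
            changed = True
            keep = [p for p in tree.points if p.id not in drop]
            kept_ids = {p.id for p in keep}
            for p in keep:
                if p.parent != -1 and p.parent not in kept_ids:
                    p.parent = -1
            tree.points = keep
    return tree


def combine_and_prune(
    trees: dict[int, SWCTree],
    layout: TileLayout,
    spacing: tuple[float, float, float],
    stack_shape: tuple[int, int, int] | None = None,
    params: GrowParams | None = None,
) -> SWCTree:
    """Merge per-tile traces into one whole-neuron SWC tree.

    Per-tile trees (tile-local micrometres) are translated by the
    resolved global coordinates and read in ascending tile order.
    Points landing on volume already occupied by earlier tiles are
    dropped — their children re-parent to the nearest already-kept point
    when it is within the connection gates — then fragments are joined
    across tile seams and the result is pruned (components < 20 μm,
    twigs < 5 points).  Ids are renumbered from 1 and the largest-radius
    point roots the tree as the soma.
    """
    if params is None:
        params = GrowParams()
    dx, dy, dz = spacing
    merged = SWCTree()
    if not trees:
        return merged
    if not layout.global_xy:
        raise ValueError("layout has no resolved global coordinates; run spanning_layout first")

    # global occupancy grid spanning every translated tile
    all_pts = []
    for tid in sorted(trees):
        gx, gy = layout.global_xy.get(tid, (0.0, 0.0))
        for p in trees[tid].points:
            all_pts.append((p.x + gx * dx, p.y + gy * dy, p.z, p.radius))
    if not all_pts:
        return merged
    arr = np.array(all_pts)
    pad = float(arr[:, 3].max()) + 2.0
    x_max, y_max, z_max = arr[:, 0].max() + pad, arr[:, 1].max() + pad, arr[:, 2].max() + pad
    if stack_shape is not None:
        Zs, Ys, Xs = stack_shape
        for tid in sorted(trees):
            gx, gy = layout.global_xy.get(tid, (0.0, 0.0))
            x_max = max(x_max, (gx + Xs) * dx)
            y_max = max(y_max, (gy + Ys) * dy)
            z_max = max(z_max, Zs * dz)
    shape = (int(np.ceil(z_max / dz)) + 1, int(np.ceil(y_max / dy)) + 1, int(np.ceil(x_max / dx)) + 1)
    grid = OccupancyGrid.for_stack(shape, spacing)

    for tid in sorted(trees):
        gx, gy = layout.global_xy.get(tid, (0.0, 0.0))
        tx, ty = gx * dx, gy * dy
        local = trees[tid]
        idmap: dict[int, int] = {}
        dropped_parent: dict[int, int] = {}  # old id -> replacement merged id (or -1)
        for p in local.points:
            moved = SWCPoint(p.id, p.type, p.x + tx, p.y + ty, p.z, p.radius, p.parent)
            if is_occupied(grid, moved):
                # re-parent children to the nearest already-kept point
                best, best_d = -1, np.inf
                for q in merged.points:
                    d = float(np.linalg.norm(moved.xyz - q.xyz))
                    if d < best_d:
                        best, best_d = q.id, d
                if best != -1 and best_d <= params.connect_max_gap_um:
                    dropped_parent[p.id] = best
                else:
                    dropped_parent[p.id] = -1
                continue
            if p.parent in idmap:
                parent = idmap[p.parent]
            elif p.parent in dropped_parent:
                parent = dropped_parent[p.parent]
            else:
                parent = -1
            new = merged.add(p.type, moved.x, moved.y, moved.z, moved.radius, parent=parent)
            idmap[p.id] = new.id
        # stamp this tile's kept structure before reading the next tile
        byid = merged.by_id()
        for old_id, new_id in idmap.items():
            np_ = byid[new_id]
            if np_.parent != -1:
                mark_occupied(grid, np_, byid[np_.parent])
            else:
                mark_occupied(grid, np_)

    connect_ends(merged, params)
    prune_tree(merged)
    if len(merged) == 0:
        return merged
    soma = max(merged.points, key=lambda p: (p.radius, -p.id))
    merged.reroot(soma.id)
    soma.type = 1
    merged.renumber()
    merged.validate()
    return merged
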