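"""End-to-end orchestration: stack → trace, tiles → whole neuron.

``trace_stack`` runs the single-stack pipeline: z-slab subdivision,
minimum projection, background removal, valley mask, skeleton paths,
depth seams, point placement, validity filtering, linking, isolated
point removal, 3D extension, thick-dendrite/soma recovery and fragment
connection.  ``trace_tiles`` traces every tile (optionally in parallel,
merged in tile-id order so the output is independent of worker count),
stitches the tiles and combines the per-tile traces into one pruned
whole-neuron SWC tree.
"""

from __future__ import annotations

import json
import re
from concurrent.futures import ProcessPoolExecutor
from pathlib import Path

import numpy as np

from .centerline import (
    DepthSeam,
    depth_seam,
    distance_map,
    link_points,
    place_points,
    skeletonize_and_split,
    z_image,
)
from .config import PipelineConfig
from .grow import (
    OccupancyGrid,
    absorb_redundant,
    connect_ends,
    extend_from_end,
    is_occupied,
    mark_occupied,
    recover_thick,
)
from .stacks import GrayStack, load_stack, min_projection, subdivide_slabs, subtract_background
from .stitch import (
    TileLayout,
    combine_and_prune,
    nominal_pair_offsets,
    pair_offset,
    parse_layout,
    prune_tree,
    spanning_layout,
    write_swc,
)
from .swc import SWCTree
from .valley import auto_tau, binary_mask, detector_bank, smooth_mask, valley_responses
from .validity import validate_and_adjust

__all__ = ["trace_stack", "trace_tiles", "trace_directory"]


def _append_chain(tree: SWCTree, points, parents, snap_tol: float, grid=None) -> list:
    """Append a linked chain, snapping onto existing near-identical points.

    Skeleton paths share their junction pixels, so chains from one mask
    meet at (near-)identical positions.  A chain point within
    ``snap_tol`` of an existing tree point reuses that point instead of
    duplicating it; subsequent chain points then hang off it, which is
    exactly how branch points form.  With an occupancy ``grid``, a point
    whose centre is already occupied is not created at all (no redundant
    points for the same piece of branch) and the chain's capsules are
    stamped as it grows.
    """
    existing = [(p.id, p.xyz) for p in tree.points]
    byid = tree.by_id()
    ids: list[int | None] = []
    for i, p in enumerate(points):
        hit = None
        for pid, xyz in existing:
            if float(np.linalg.norm(p.xyz - xyz)) <= snap_tol:
                hit = pid
                break
        if hit is not None:
            ids.append(hit)
            continue
        parent_id = -1
        if parents[i] != -1 and ids[parents[i]] is not None:
            parent_id = ids[parents[i]]
        if grid is not None and is_occupied(grid, p):
            # densely spaced chain points may sit inside their own
            # predecessor's capsule; only foreign occupancy suppresses
            own = (
                parent_id != -1
                and float(np.linalg.norm(p.xyz - byid[parent_id].xyz))
                <= byid[parent_id].radius + p.radius
            )
            if not own:
                ids.append(None)
                continue
        new = tree.add(3, p.x, p.y, p.z, p.radius, parent=parent_id)
        existing.append((new.id, new.xyz))
        byid[new.id] = new
        ids.append(new.id)
        if grid is not None:
            if parent_id != -1:
                mark_occupied(grid, new, byid[parent_id])
            else:
                mark_occupied(grid, new)
    return ids


def _walk_path(stack, path, dmap, seam, config: PipelineConfig, vparams) -> list:
    """Place and validate points incrementally along one xy-path.

    The gap to the next point is roughly the sum of the last *adjusted*
    radius and the local distance-map radius, halved when the radius is
    changing rapidly.  A candidate that fails the validity test does
    not advance the chain: the walk retries pixel by pixel, so sparse
    valid structure (e.g. beads along a fragmented thin branch) is
    still sampled point by point.
    """
    from .centerline import TracePoint

    dx, dy, dz = config.spacing
    ys = np.array([p[0] for p in path.pixels])
    xs = np.array([p[1] for p in path.pixels])
    radii = np.maximum(dmap[ys, xs], 0.5 * dx)
    steps = np.hypot(np.diff(xs) * dx, np.diff(ys) * dy)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    valid: list = []
    last_arc, last_r = -np.inf, None
    for i in range(len(path.pixels)):
        if valid and i < len(path.pixels) - 1:
            gap = last_r + radii[i]
            if abs(radii[i] - last_r) > config.place_rapid_dr_frac * min(radii[i], last_r):
                gap *= 0.5
            if arc[i] - last_arc < gap:
                continue
        cand = TracePoint(xs[i] * dx, ys[i] * dy, seam.z_index[i] * dz, radii[i])
        adj = validate_and_adjust(stack, cand, vparams, stringency="standard")
        if adj is None:
            continue
        # adjustment can collapse neighbouring candidates onto one spot
        if valid and float(np.linalg.norm(adj.xyz - valid[-1].xyz)) < 0.5 * dx:
            last_arc = arc[i]
            continue
        valid.append(adj)
        last_arc, last_r = arc[i], adj.radius
    return valid


def _trace_slab(
    stack: GrayStack,
    slab: tuple[int, int],
    config: PipelineConfig,
    tree: SWCTree,
    grid: OccupancyGrid | None = None,
) -> None:
    """Trace one z-slab of a stack, appending linked chains to ``tree``."""
    z_lo, z_hi = slab
    dx, dy, dz = config.spacing
    sub = GrayStack(stack.voxels[z_lo:z_hi], stack.spacing)
    proj = subtract_background(min_projection(sub), config.background_scale_um)
    bank = detector_bank(config.valley_scale_um, config.valley_n_orientations, (dx, dy))
    field = valley_responses(proj, bank)
    tau = auto_tau(field, config.valley_tau_k)
    mask = smooth_mask(
        binary_mask(field, tau, config.valley_delta_frac, proj, config.validity_sigma),
        config.mask_min_speck_px,
        config.mask_closing_radius_px,
    )
    if not mask.pixels.any():
        return
    dmap = distance_map(mask, (dx, dy))
    vparams = config.validity_params()
    for path in skeletonize_and_split(mask):
        seam = depth_seam(z_image(sub, path), config.seam_max_step)
        seam = DepthSeam(seam.z_index + z_lo, seam.cost)
        valid = _walk_path(stack, path, dmap, seam, config, vparams)
        if not valid:
            continue
        parents = link_points(
            valid, config.link_max_gap_um, config.link_max_angle_deg, config.link_max_dz_um
        )
        _append_chain(tree, valid, parents, snap_tol=dx, grid=grid)


def trace_stack(
    stack: GrayStack | str | Path,
    config: PipelineConfig | None = None,
    final_prune: bool = True,
) -> SWCTree:
    """Trace one stack into an SWC tree (stack-local μm coordinates)."""
    if config is None:
        config = PipelineConfig()
    if not isinstance(stack, GrayStack):
        stack = load_stack(stack, config.spacing, darkfield=config.darkfield)
    tree = SWCTree()
    if stack.is_constant:
        return tree
    grid = OccupancyGrid.for_stack(stack.shape, stack.spacing)
    n_slabs = min(config.slabs_n, stack.depth)
    for slab in subdivide_slabs(stack.depth, n_slabs):
        _trace_slab(stack, slab, config, tree, grid)

    gparams = config.grow_params()
    # give genuinely fragmented structure (beading) a chance to link up
    # before the isolated-point noise filter runs
    connect_ends(tree, gparams)
    deg = tree.degree()
    tree.points = [p for p in tree.points if deg[p.id] > 0]

    # recover soma/thick dendrites the valley mask missed, then extend
    # in 3D from every end (including freshly recovered ones)
    proj = subtract_background(min_projection(stack), config.background_scale_um)
    for chain in recover_thick(stack, proj, tree, gparams):
        parents = link_points(
            chain,
            max_gap_um=2.0 * config.validity_r_max_um,
            max_angle_deg=config.link_max_angle_deg,
            max_dz_um=config.link_max_dz_um,
        )
        _append_chain(tree, chain, parents, snap_tol=config.spacing_dx)
    absorb_redundant(tree)

    # absorption and recovery changed the structure; rebuild occupancy
    grid = OccupancyGrid.for_stack(stack.shape, stack.spacing)
    byid = tree.by_id()
    for p in tree.points:
        if p.parent != -1:
            mark_occupied(grid, p, byid[p.parent])
        else:
            mark_occupied(grid, p)
    extend_from_end(stack, tree, grid, gparams)

    connect_ends(tree, gparams)
    if final_prune:
        prune_tree(tree, config.prune_min_component_um, config.prune_min_twig_points)
        if len(tree) > 0:
            soma = max(tree.points, key=lambda p: (p.radius, -p.id))
            tree.reroot(soma.id)
            soma.type = 1
    tree.renumber()
    tree.validate()
    return tree


def _trace_tile_task(args) -> tuple[int, SWCTree]:
    tid, stack, config = args
    return tid, trace_stack(stack, config, final_prune=False)


def trace_tiles(
    tiles: dict[int, GrayStack],
    layout: TileLayout,
    config: PipelineConfig | None = None,
) -> tuple[SWCTree, TileLayout]:
    """Trace, stitch and combine a tiled scene into one SWC tree.

    Per-tile tracing is an embarrassingly parallel map; results are
    merged in ascending tile-id order, so the output is identical for
    any worker count.
    """
    if config is None:
        config = PipelineConfig()
    if not tiles:
        raise ValueError("no tiles supplied")
    missing = [t for t in layout.tiles if t not in tiles]
    if missing:
        raise ValueError(f"missing tile stacks: {missing}")
    tasks = [(tid, tiles[tid], config) for tid in sorted(tiles)]
    if config.n_workers > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=config.n_workers) as pool:
            results = list(pool.map(_trace_tile_task, tasks))
    else:
        results = [_trace_tile_task(t) for t in tasks]
    trees = dict(sorted(results))

    first = tiles[sorted(tiles)[0]]
    tile_shape_2d = first.shape[1:]
    nominal = nominal_pair_offsets(layout, tile_shape_2d)
    for pair in layout.adjacent_pairs():
        a, b = pair
        off, w = pair_offset(tiles[a], tiles[b], nominal[pair])
        layout.pair_offsets[pair] = (off, w)
    spanning_layout(layout)
    tree = combine_and_prune(trees, layout, config.spacing, first.shape, config.grow_params())
    return tree, layout


def trace_directory(
    data_dir: str | Path,
    config: PipelineConfig | None = None,
    common: str | None = None,
) -> tuple[Path, Path]:
    """Trace a directory of tile TIFFs plus a ``tileSequences.txt`` layout.

    Tiles are named ``<common><id>.tif``; writes ``<common>.auto.swc``
    and a ``<common>.json`` sidecar (global tile coordinates and pair
    weights) into the directory, returning both paths.
    """
    if config is None:
        config = PipelineConfig()
    data_dir = Path(data_dir)
    layout_path = data_dir / "tileSequences.txt"
    if not layout_path.exists():
        raise FileNotFoundError(f"no tileSequences.txt in {data_dir}")
    layout = parse_layout(layout_path.read_text())
    tifs = sorted(data_dir.glob("*.tif")) + sorted(data_dir.glob("*.tiff"))
    pattern = re.compile(r"^(.*?)(\d+)\.tiff?$")
    found: dict[int, Path] = {}
    commons = set()
    for path in tifs:
        m = pattern.match(path.name)
        if m:
            commons.add(m.group(1))
            found[int(m.group(2))] = path
    if not found:
        raise FileNotFoundError(f"no numbered tile TIFFs in {data_dir}")
    if common is None:
        common = sorted(commons)[0] or "neuron"
    missing = [t for t in layout.tiles if t not in found]
    if missing:
        raise FileNotFoundError(f"layout names tiles with no TIFF: {missing}")
    tiles = {
        t: load_stack(found[t], config.spacing, darkfield=config.darkfield, origin_tile=str(t))
        for t in layout.tiles
    }
    tree, layout = trace_tiles(tiles, layout, config)
    swc_path = data_dir / f"{common.rstrip('._-') or 'neuron'}.auto.swc"
    swc_path.write_text(write_swc(tree))
    sidecar = {
        "global_xy": {str(t): list(xy) for t, xy in sorted(layout.global_xy.items())},
        "pair_offsets": {
            f"{a}-{b}": {"offset": list(off), "weight": w}
            for (a, b), (off, w) in sorted(layout.pair_offsets.items())
        },
    }
    json_path = data_dir / f"{common.rstrip('._-') or 'neuron'}.json"
    json_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return swc_path, json_path
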