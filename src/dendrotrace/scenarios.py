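"""Canonical synthetic benchmark scenes.

Frozen study conditions used by the test suite and the reproduction
script: straight tubes across the thin-to-thick radius range, a seeded
soma + three-bifurcation tree, a fragmented ("beaded") thin branch and
a jittered two-tile mosaic.  Image geometry uses 0.2 μm pixels and
0.5 μm plane spacing throughout, matching a high-NA bright-field setup
scaled to desk-size stacks.
"""

from __future__ import annotations

from .stacks import GrayStack
from .swc import SWCTree
from .synthetic import RenderParams, TileSet, TreeSpec, make_tiles, make_tree, render_stack

SPACING = (0.2, 0.2, 0.5)

__all__ = [
    "SPACING",
    "straight_tube_scene",
    "bifurcation_scene",
    "beaded_scene",
    "tiled_scene",
]


def straight_tube_scene(radius_um: float, noise_sd: float = 0.0, seed: int = 1):
    """One straight tube along x (22.5 μm of cable) in a 25.6 μm field."""
    tree = SWCTree()
    a = tree.add(3, 1.5, 12.8, 8.0, radius_um)
    tree.add(3, 24.0, 12.8, 8.0, radius_um, parent=a.id)
    stack, truth = render_stack(
        tree, (32, 128, 128), SPACING, RenderParams(noise_sd=noise_sd, seed=seed)
    )
    return stack, truth


def bifurcation_scene(seed: int = 0):
    """Soma plus a balanced tree with three bifurcations (four tips)."""
    tree = make_tree(
        TreeSpec(
            levels=2,
            root=(5.0, 16.0, 8.0),
            segment_length_um=12.0,
            radius_taper=0.8,
            soma_radius_um=3.0,
        ),
        seed=seed,
    )
    stack, truth = render_stack(
        tree, (32, 160, 192), SPACING, RenderParams(noise_sd=0.02, seed=seed)
    )
    return stack, truth


def beaded_scene(seed: int = 0):
    """Thin branch fully fragmented into beads with 2 μm faint gaps."""
    tree = SWCTree()
    prev = tree.add(3, 2.0, 12.8, 8.0, 0.4)
    for x in (7.2, 12.4, 17.6, 22.8, 28.0):
        prev = tree.add(3, x, 12.8, 8.0, 0.4, parent=prev.id)
    stack, truth = render_stack(
        tree,
        (32, 128, 160),
        SPACING,
        RenderParams(bead_fraction=1.0, bead_gap_um=2.0, noise_sd=0.01, seed=seed),
    )
    return stack, truth


def tiled_scene(seed: int = 5, jitter_px: int = 5):
    """One-bifurcation neuron split into two overlapping jittered tiles."""
    tree = make_tree(
        TreeSpec(
            levels=1,
            root=(4.0, 12.8, 8.0),
            segment_length_um=16.0,
            radius_taper=0.85,
            soma_radius_um=3.0,
        ),
        seed=seed,
    )
    stack, truth = render_stack(
        tree, (32, 128, 224), SPACING, RenderParams(noise_sd=0.02, seed=seed)
    )
    tiles = make_tiles(stack, 2, 1, overlap_pct=20, jitter_px=jitter_px, seed=seed)
    return stack, truth, tiles
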