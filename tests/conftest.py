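import numpy as np
import pytest

from dendrotrace.config import PipelineConfig
from dendrotrace.swc import SWCTree
from dendrotrace.synthetic import RenderParams, TreeSpec, make_tree, render_stack

SPACING = (0.2, 0.2, 0.5)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


def straight_tube(radius: float, x0: float = 1.5, x1: float = 24.0, y: float = 12.8, z: float = 8.0) -> SWCTree:
    """Two-point tree describing one straight tube along x."""
    tree = SWCTree()
    a = tree.add(3, x0, y, z, radius)
    tree.add(3, x1, y, z, radius, parent=a.id)
    return tree


@pytest.fixture(scope="session")
def clean_tube_stack():
    """Noise-free rendered 1 um tube plus its ground truth."""
    tree = straight_tube(1.0)
    stack, truth = render_stack(tree, (32, 128, 128), SPACING, RenderParams(seed=1))
    return stack, truth


@pytest.fixture(scope="session")
def bifurcating_scene():
    """Seeded soma + three-bifurcation tree rendered with mild noise."""
    tree = make_tree(
        TreeSpec(levels=2, root=(5.0, 16.0, 8.0), segment_length_um=12.0,
                 radius_taper=0.8, soma_radius_um=3.0),
        seed=0,
    )
    stack, truth = render_stack(tree, (32, 160, 192), SPACING, RenderParams(noise_sd=0.02, seed=0))
    return stack, truth
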