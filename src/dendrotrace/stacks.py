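"""Image-stack loading, grayscale normalization, projections and z-slabs.

A neuron is imaged as one or more tiles of multi-page TIFF stacks.  Every
downstream stage consumes a :class:`GrayStack`: a 3D intensity volume in
[0, 1] indexed ``(z, y, x)`` with physical voxel spacing in micrometres.
Stained structures are dark on a bright background (bright-field
convention); dark-field input is inverted on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

__all__ = [
    "GrayStack",
    "Projection",
    "load_stack",
    "to_gray_unit",
    "min_projection",
    "subtract_background",
    "subdivide_slabs",
]

# ITU-R 601 luma weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayStack:
    """3D grayscale volume with physical voxel spacing.

    Attributes
    ----------
    voxels : ndarray, shape (Z, Y, X)
        Intensities in [0, 1]; after normalization the maximum is 1
        unless the stack is constant.
    spacing : tuple of float
        ``(dx, dy, dz)`` voxel size in micrometres; all strictly positive.
    origin_tile : str or None
        Identifier of the tile this stack came from, if any.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin_tile: str | None = None
    is_constant: bool = field(default=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) volume, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack contains non-finite intensities")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def depth(self) -> int:
        return self.voxels.shape[0]


@dataclass
class Projection:
    """2D minimum-intensity projection of a stack or z-slab.

    ``pixels[y, x]`` is the darkest voxel over the slab's z indices at
    that xy position (before any background removal).
    """

    pixels: np.ndarray
    slab: tuple[int, int]
    spacing: tuple[float, float]
    background_removed: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("projection must be 2D")


def load_stack(
    path,
    spacing: tuple[float, float, float],
    darkfield: bool = False,
    origin_tile: str | None = None,
) -> GrayStack:
    """Read a multi-page TIFF into a normalized :class:`GrayStack`.

    Pages become z-planes in file order.  RGB pages are converted to
    luminance (ITU-R 601 weights) before scaling; 8/16-bit integer data
    are treated as linear intensity.
    """
    try:
        raw = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - message formatting
        raise OSError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 2:
        raw = raw[None]
    if raw.ndim == 4:
        if raw.shape[-1] not in (3, 4):
            raise ValueError(f"unsupported page layout in {path!r}: shape {raw.shape}")
        raw = raw[..., :3] @ _LUMA
    if raw.ndim != 3:
        raise ValueError(f"inconsistent page shapes in {path!r}: shape {raw.shape}")
    stack = GrayStack(raw.astype(np.float64), spacing, origin_tile=origin_tile)
    return to_gray_unit(stack, darkfield=darkfield)


def to_gray_unit(stack: GrayStack, darkfield: bool = False) -> GrayStack:
    """Normalize intensities to unit maximum, inverting dark-field input.

    Dark-field images (bright structures on dark background) are inverted
    (``i -> max - i``) so that neurites are dark, then rescaled so the
    maximum intensity is 1.  A constant stack is returned unchanged with
    a warning and flagged so the pipeline can emit an empty trace.
    """
    v = stack.voxels.astype(np.float64)
    if darkfield:
        v = v.max() - v
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("constant-intensity stack; returning unchanged", stacklevel=2)
        return replace(stack, voxels=np.clip(v, 0.0, 1.0), is_constant=True)
    if lo < 0:
        v = v - lo
    v = v / v.max()
    return replace(stack, voxels=v, is_constant=False)


def min_projection(stack: GrayStack, slab: tuple[int, int] | None = None) -> Projection:
    """Per-pixel minimum over a half-open z range ``[z_lo, z_hi)``.

    The darkest voxel wins at every xy position, which reveals dark
    neurites at any depth within the slab.
    """
    if slab is None:
        slab = (0, stack.depth)
    z_lo, z_hi = slab
    if not (0 <= z_lo < z_hi <= stack.depth):
        raise ValueError(f"empty or out-of-range slab {slab} for depth {stack.depth}")
    pixels = stack.voxels[z_lo:z_hi].min(axis=0)
    return Projection(pixels, (z_lo, z_hi), stack.spacing[:2])


def subtract_background(projection: Projection, smoothing_scale_um: float) -> Projection:
    """Remove slowly varying illumination from a projection.

    The projection is blurred with a Gaussian whose scale (in μm) is much
    larger than a neurite diameter, and the blur is subtracted.  The
    difference is then shifted by the blurred image's mean and clipped to
    [0, 1], so the output lives on the same intensity scale as the input
    and downstream absolute thresholds keep their meaning.
    """
    if smoothing_scale_um <= 0:
        raise ValueError("smoothing scale must be positive")
    dx, dy = projection.spacing
    sigma = (smoothing_scale_um / dy, smoothing_scale_um / dx)
    blurred = gaussian_filter(projection.pixels, sigma, mode="nearest")
    out = projection.pixels - blurred + blurred.mean()
    out = np.clip(out, 0.0, 1.0)
    return Projection(out, projection.slab, projection.spacing, background_removed=True)


def subdivide_slabs(depth: int, n_slabs: int) -> list[tuple[int, int]]:
    """Split ``[0, depth)`` into ``n_slabs`` contiguous half-open ranges.

    Heights differ by at most one plane; the taller slabs come first.
    Tracing each slab separately mitigates occlusion in the full-depth
    projection when many branches share a stack.
    """
    if not 1 <= n_slabs <= depth:
        raise ValueError(f"n_slabs must be in [1, {depth}], got {n_slabs}")
    base, extra = divmod(depth, n_slabs)
    ranges = []
    lo = 0
    for i in range(n_slabs):
        hi = lo + base + (1 if i < extra else 0)
        ranges.append((lo, hi))
        lo = hi
    return ranges
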