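"""Oriented valley detection and the binary neurite mask.

Viewing intensity as height, neurites in a background-removed projection
are valleys: an oriented dark band flanked by two bright bands.  A bank
of zero-sum oriented stencils is correlated with the image; per pixel the
maximum response over orientations (``lambda1``), the minimum
(``lambda2``) and the argmax orientation are kept.  A line pixel has
``lambda1`` large and ``lambda2`` small; a blob has both large because no
orientation is privileged; background has both near zero.  Thresholding
``lambda1`` while requiring anisotropy (``lambda1 - lambda2`` large
relative to ``lambda1``) therefore keeps lines but rejects blobs and
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk, opening, remove_small_objects

__all__ = [
    "ValleyField",
    "Mask",
    "detector_bank",
    "valley_responses",
    "binary_mask",
    "auto_tau",
    "smooth_mask",
]


@dataclass
class ValleyField:
    """Per-pixel extreme detector responses and the argmax orientation."""

    lambda1: np.ndarray
    lambda2: np.ndarray
    theta1: np.ndarray
    angles: np.ndarray


@dataclass
class Mask:
    """Binary neurite mask with the provenance of its construction."""

    pixels: np.ndarray
    provenance: str = "valley"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)


def _mother_kernel(scale_um: float, spacing: tuple[float, float], theta: float) -> np.ndarray:
    """One oriented valley stencil.

    Second derivative across the band of an anisotropic Gaussian
    (sigma_across = scale/2, sigma_along = 2*scale), rotated to ``theta``
    and mean-subtracted so the stencil sums to zero.  The central weights
    are negative and the flank weights positive, so a dark band aligned
    with the stencil produces a large positive response.
    """
    dx, dy = spacing
    sigma_across = scale_um / 2.0
    sigma_along = 2.0 * scale_um
    half_um = 2.5 * sigma_along
    nx = max(int(np.ceil(half_um / dx)), 2)
    ny = max(int(np.ceil(half_um / dy)), 2)
    ys, xs = np.mgrid[-ny : ny + 1, -nx : nx + 1]
    x_um = xs * dx
    y_um = ys * dy
    # rotate coordinates: theta is the band's orientation; u runs across
    # the band (perpendicular to theta), v along it
    u = -x_um * np.sin(theta) + y_um * np.cos(theta)
    v = x_um * np.cos(theta) + y_um * np.sin(theta)
    g = np.exp(-0.5 * (u / sigma_across) ** 2 - 0.5 * (v / sigma_along) ** 2)
    kernel = (u**2 / sigma_across**4 - 1.0 / sigma_across**2) * g
    kernel -= kernel.mean()
    # unit L2 norm keeps responses comparable across scales and spacings
    kernel /= np.linalg.norm(kernel)
    return kernel


def detector_bank(
    scale_um: float,
    n_orientations: int,
    spacing: tuple[float, float],
) -> list[np.ndarray]:
    """Build the oriented stencil bank covering [0, pi).

    ``scale_um`` is the width of the dark band the detector is tuned to
    (a thin-dendrite diameter); orientation k is at angle ``k*pi/n``.
    """
    if scale_um <= 0:
        raise ValueError("detector scale must be positive")
    if scale_um / 2.0 < min(spacing) / 2.0:
        raise ValueError(f"detector scale {scale_um} um is below one pixel {spacing}")
    if n_orientations < 4:
        raise ValueError("need at least 4 orientations")
    angles = np.arange(n_orientations) * np.pi / n_orientations
    return [_mother_kernel(scale_um, spacing, t) for t in angles]


def valley_responses(projection, bank: list[np.ndarray]) -> ValleyField:
    """Correlate the projection with every stencil in the bank.

    Returns per-pixel ``lambda1`` (max over orientations), ``lambda2``
    (min) and ``theta1`` (argmax orientation in [0, pi)).  Borders are
    handled by reflective padding.
    """
    pixels = projection.pixels if hasattr(projection, "pixels") else np.asarray(projection)
    n = len(bank)
    angles = np.arange(n) * np.pi / n
    responses = np.empty((n,) + pixels.shape)
    for i, kernel in enumerate(bank):
        responses[i] = ndimage.correlate(pixels, kernel, mode="reflect")
    idx1 = responses.argmax(axis=0)
    lambda1 = np.take_along_axis(responses, idx1[None], axis=0)[0]
    lambda2 = responses.min(axis=0)
    theta1 = angles[idx1]
    return ValleyField(lambda1, lambda2, theta1, angles)


def auto_tau(field: ValleyField, k: float = 6.0) -> float:
    """Robust response threshold: median + k * MAD of ``lambda1``.

    Most pixels are background, so the median and MAD of ``lambda1``
    estimate the response noise floor; ``k`` sets the detection
    stringency.
    """
    lam = field.lambda1.ravel()
    med = np.median(lam)
    mad = np.median(np.abs(lam - med))
    return float(med + k * mad)


def binary_mask(
    field: ValleyField,
    tau1: float,
    delta_frac: float = 0.5,
    projection=None,
    dark_sigma: float = 0.03,
) -> Mask:
    """Threshold the valley field into a binary mask.

    A pixel is kept iff ``lambda1 >= tau1`` and
    ``lambda1 - lambda2 >= delta_frac * lambda1``.  The second gate
    rejects isotropic responders (blobs, craters) whose min-orientation
    response is nearly as large as the max.  When the source
    ``projection`` is supplied, a darkness gate additionally requires
    the pixel itself to sit below the background level minus
    ``dark_sigma``: the oriented detectors respond over a neighbourhood,
    but a valley-floor pixel must itself be dark.
    """
    keep = field.lambda1 >= tau1
    keep &= (field.lambda1 - field.lambda2) >= delta_frac * field.lambda1
    if projection is not None:
        pix = projection.pixels if hasattr(projection, "pixels") else np.asarray(projection)
        keep &= pix < np.median(pix) - dark_sigma
    return Mask(keep, provenance="valley")


def smooth_mask(mask: Mask, min_speck_px: int = 8, closing_radius_px: int = 1) -> Mask:
    """Drop small speckles and smooth ragged boundaries.

    Connected components below ``min_speck_px`` pixels are removed, then
    a morphological closing followed by opening with a disk of
    ``closing_radius_px`` rounds the boundary.
    """
    pixels = mask.pixels.copy()
    if min_speck_px > 1:
        pixels = remove_small_objects(pixels, max_size=min_speck_px - 1, connectivity=2)
    if closing_radius_px > 0 and pixels.any():
        footprint = disk(closing_radius_px)
        pixels = closing(pixels, footprint)
        pixels = opening(pixels, footprint)
        # opening can re-create specks from pinched-off corners
        if min_speck_px > 1:
            pixels = remove_small_objects(pixels, max_size=min_speck_px - 1, connectivity=2)
    return Mask(pixels, provenance=mask.provenance)
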