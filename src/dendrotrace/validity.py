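"""SWC-point validity testing and iterative adjustment.

A candidate point is checked against the image itself: a square patch is
cut from the point's z-plane, detrended by subtracting a least-squares
plane (so illumination tilt cannot masquerade as structure), and
intensity profiles through the centre are taken along eight directions.
A genuine neurite cross-section shows a significant *inverse peak* in at
least one profile: the smoothed profile must rise above the half-way
threshold on both flanks and dip below the baseline minus ``depth_k``
fluctuation units.  The narrowest valid peak defines the radius (half
its width) and re-centres the point; the profile orthogonal to the
chosen one must also be dark near the centre, which rejects points
sitting on the edge of a thick dendrite or soma.  The adjustment is
iterated a fixed number of times; a point that drifts more than twice
its original radius, or whose radius leaves the plausible dendrite
range, is declared invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

from .centerline import TracePoint, refine_z

__all__ = [
    "ValidityParams",
    "ProfileSet",
    "PeakVerdict",
    "detrended_patch",
    "extract_profiles",
    "inverse_peak",
    "choose_profile",
    "orthogonal_darkness",
    "validate_and_adjust",
]

N_DIRECTIONS = 8


@dataclass
class ValidityParams:
    """Tunables of the validity test (all lengths in micrometres).

    ``sigma`` characterises intensity fluctuations; the baseline is the
    top ``baseline_top_frac`` intensity value of the patch (i.e. the
    (1 - frac) quantile); a peak is deep enough when its minimum falls
    below baseline - ``depth_k``·sigma (``relaxed_k`` replaces
    ``depth_k`` at relaxed stringency, used during 3D extension to pick
    up faint branches).
    """

    sigma: float = 0.03
    baseline_top_frac: float = 0.20
    depth_k: float = 2.0
    relaxed_k: float = 1.0
    patch_floor_um: float = 4.0
    patch_radius_mult: float = 4.0
    r_min_um: float = 0.2
    r_max_um: float = 10.0
    max_shift_mult: float = 2.0
    n_iter: int = 3
    profile_smooth_sigma: float = 2.0  # samples
    z_window: int = 3


@dataclass
class ProfileSet:
    """Intensity profiles through a patch centre along eight directions.

    Directions are multiples of pi/8 over a half-turn; each profile runs
    along the full line (both senses), sampled at one-pixel steps with
    bilinear interpolation, centre sample aligned across profiles.
    """

    directions: np.ndarray
    raw: np.ndarray       # (8, L)
    smoothed: np.ndarray  # (8, L)
    step_um: float
    patch_side_um: float

    @property
    def center(self) -> int:
        return self.raw.shape[1] // 2


@dataclass
class PeakVerdict:
    """Outcome of the inverse-peak test on one profile."""

    significant: bool
    center_offset: float = 0.0  # um along the profile, signed
    width: float = 0.0          # um, steepest-descent to steepest-ascent
    depth: float = 1.0          # intensity at the minimum


def _plane_index(stack, point: TracePoint) -> tuple[int, int, int]:
    dx, dy, dz = stack.spacing
    Z, Y, X = stack.shape
    ix = min(max(int(round(point.x / dx)), 0), X - 1)
    iy = min(max(int(round(point.y / dy)), 0), Y - 1)
    iz = min(max(int(round(point.z / dz)), 0), Z - 1)
    return ix, iy, iz


def detrended_patch(stack, point: TracePoint, params: ValidityParams) -> tuple[np.ndarray, bool]:
    """Square patch around the point in its z-plane, tilt removed.

    Side length is ``patch_radius_mult`` × radius or ``patch_floor_um``,
    whichever is greater.  A least-squares plane in (x, y) is subtracted
    and the residual affinely rescaled to the patch's original intensity
    range.  Returns the patch and a flag marking border clipping (the
    patch is then padded by edge replication).
    """
    dx, dy, dz = stack.spacing
    _, _, iz = _plane_index(stack, point)
    plane = stack.voxels[iz]
    side_um = max(params.patch_radius_mult * point.radius, params.patch_floor_um)
    n_half = max(int(np.ceil(side_um / 2.0 / dx)), 2)
    cy, cx = point.y / dy, point.x / dx
    offs = np.arange(-n_half, n_half + 1, dtype=float)
    rows = cy + offs[:, None] + 0.0 * offs[None, :]
    cols = cx + 0.0 * offs[:, None] + offs[None, :]
    clipped = bool(
        rows.min() < 0 or cols.min() < 0
        or rows.max() > plane.shape[0] - 1 or cols.max() > plane.shape[1] - 1
    )
    patch = map_coordinates(plane, [rows, cols], order=1, mode="nearest")
    # least-squares plane fit in (x, y)
    yy, xx = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]].astype(float)
    A = np.column_stack([np.ones(patch.size), xx.ravel(), yy.ravel()])
    coef, *_ = np.linalg.lstsq(A, patch.ravel(), rcond=None)
    resid = patch - (A @ coef).reshape(patch.shape)
    lo, hi = patch.min(), patch.max()
    rlo, rhi = resid.min(), resid.max()
    if rhi - rlo > 1e-9:  # a pure plane leaves only float noise: stay flat
        patch = (resid - rlo) / (rhi - rlo) * (hi - lo) + lo
    else:
        patch = np.full_like(patch, patch.mean())
    return patch, clipped


def extract_profiles(patch: np.ndarray, step_um: float, params: ValidityParams) -> ProfileSet:
    """Sample intensity profiles through the patch centre in 8 directions."""
    n_half = patch.shape[0] // 2
    offs = np.arange(-n_half, n_half + 1, dtype=float)
    directions = np.arange(N_DIRECTIONS) * np.pi / N_DIRECTIONS
    raw = np.empty((N_DIRECTIONS, offs.size))
    for k, theta in enumerate(directions):
        rows = n_half + offs * np.sin(theta)
        cols = n_half + offs * np.cos(theta)
        raw[k] = map_coordinates(patch, [rows, cols], order=1, mode="nearest")
    smoothed = gaussian_filter1d(raw, params.profile_smooth_sigma, axis=1, mode="nearest")
    return ProfileSet(directions, raw, smoothed, step_um, patch.shape[0] * step_um)


def inverse_peak(
    smoothed: np.ndarray,
    baseline: float,
    params: ValidityParams,
    depth_k: float | None = None,
    step_um: float = 1.0,
) -> PeakVerdict:
    """Judge whether a smoothed profile carries a significant inverse peak.

    Two criteria: (a) the profile climbs above the half-way threshold
    (midpoint of its own min and max) on both sides of the minimum —
    i.e. the dip has two flanks; (b) the minimum lies below
    baseline - depth_k·sigma.  The width is measured between the
    steepest-descent and steepest-ascent points of the dip, located as
    the extrema of the lightly re-smoothed derivative.
    """
    if depth_k is None:
        depth_k = params.depth_k
    smoothed = np.asarray(smoothed, dtype=float)
    n = smoothed.size
    m = int(np.argmin(smoothed))
    depth = float(smoothed[m])
    half = 0.5 * (smoothed.max() + smoothed.min())
    if m == 0 or m == n - 1:
        return PeakVerdict(False, depth=depth)
    left_ok = smoothed[: m + 1].max() > half
    right_ok = smoothed[m:].max() > half
    deep_ok = depth < baseline - depth_k * params.sigma
    if not (left_ok and right_ok and deep_ok):
        return PeakVerdict(False, depth=depth)
    deriv = np.gradient(smoothed)
    deriv = gaussian_filter1d(deriv, 1.0, mode="nearest")
    # flank search is confined to the dip itself: between the minimum
    # and the nearest half-threshold crossings on either side, so a
    # second dip further out (another bead, a neighbouring branch)
    # cannot masquerade as this peak's flank
    above = smoothed >= half
    left_idx = np.nonzero(above[: m + 1])[0]
    lo = int(left_idx[-1]) if left_idx.size else 0
    right_idx = np.nonzero(above[m:])[0]
    hi = m + int(right_idx[0]) if right_idx.size else n - 1
    i_desc = lo + int(np.argmin(deriv[lo : m + 1]))  # steepest descent, left flank
    i_asc = m + int(np.argmax(deriv[m : hi + 1]))    # steepest ascent, right flank
    width = (i_asc - i_desc) * step_um
    if width <= 0:
        return PeakVerdict(False, depth=depth)
    center = 0.5 * (i_desc + i_asc)
    offset = (center - n // 2) * step_um
    return PeakVerdict(True, center_offset=offset, width=float(width), depth=depth)


def choose_profile(verdicts: list[PeakVerdict]) -> int | None:
    """Pick the significant profile with minimum width (tie: lower index)."""
    best, best_w = None, np.inf
    for i, v in enumerate(verdicts):
        if v.significant and v.width < best_w:
            best, best_w = i, v.width
    return best


def orthogonal_darkness(
    profiles: ProfileSet,
    chosen: int,
    radius_um: float,
    params: ValidityParams,
) -> bool:
    """Check the orthogonal profile is dark within half a radius of centre.

    A point on the rim of a thick dark structure has a valid-looking dip
    along one line but stays bright along the orthogonal one; requiring
    min(orthogonal) < max(chosen) + sigma within ±r/2 rejects it.
    """
    orth = (chosen + N_DIRECTIONS // 2) % N_DIRECTIONS
    c = profiles.center
    half_r_samples = max(int(round(radius_um / 2.0 / profiles.step_um)), 1)
    lo = max(0, c - half_r_samples)
    hi = min(profiles.raw.shape[1], c + half_r_samples + 1)
    chosen_max = profiles.smoothed[chosen, lo:hi].max()
    orth_min = profiles.smoothed[orth, lo:hi].min()
    return bool(orth_min < chosen_max + params.sigma)


def validate_and_adjust(
    stack,
    point: TracePoint,
    params: ValidityParams | None = None,
    stringency: str = "standard",
) -> TracePoint | None:
    """Run the full validity test, adjusting position and radius.

    Iterates patch → profiles → peak test → narrowest-peak choice →
    orthogonal-darkness gate ``n_iter`` times.  Each pass re-centres the
    point along the chosen profile, sets the radius to half the peak
    width and snaps z to the nearby intensity minimum.  Returns the
    adjusted point, or ``None`` if the point is invalid: no significant
    peak, bright orthogonal profile, total xy drift beyond
    ``max_shift_mult`` × original radius, or final radius outside
    [``r_min_um``, ``r_max_um``].
    """
    if params is None:
        params = ValidityParams()
    if stringency not in ("standard", "relaxed"):
        raise ValueError(f"unknown stringency {stringency!r}")
    depth_k = params.depth_k if stringency == "standard" else params.relaxed_k
    dx = stack.spacing[0]
    orig = point
    cur = replace(point)
    for _ in range(params.n_iter):
        # if the centre is dark but the patch shows no flanks, the
        # structure is wider than the current radius guess: enlarge the
        # patch and look again before giving up
        k = None
        for enlarge in range(3):
            probe = replace(cur, radius=cur.radius * (2.0**enlarge))
            patch, _ = detrended_patch(stack, probe, params)
            baseline = float(np.quantile(patch, 1.0 - params.baseline_top_frac))
            profiles = extract_profiles(patch, dx, params)
            verdicts = [
                inverse_peak(profiles.smoothed[k2], baseline, params, depth_k, dx)
                for k2 in range(N_DIRECTIONS)
            ]
            k = choose_profile(verdicts)
            if k is not None:
                break
            c = profiles.center
            centre_dark = profiles.smoothed[:, c].min() < baseline - depth_k * params.sigma
            if not centre_dark or probe.radius * 2.0 > params.r_max_um:
                break
        if k is None:
            return None
        v = verdicts[k]
        new_r = v.width / 2.0
        if not orthogonal_darkness(profiles, k, max(new_r, cur.radius), params):
            return None
        theta = profiles.directions[k]
        cur = TracePoint(
            cur.x + v.center_offset * np.cos(theta),
            cur.y + v.center_offset * np.sin(theta),
            cur.z,
            new_r,
        )
        # a thick structure is dark over many planes, so its z profile
        # has a flat noisy bottom; smooth harder the thicker the point
        z_sigma = max(2.0, cur.radius / stack.spacing[2])
        cur = replace(cur, z=refine_z(stack, cur, params.z_window, z_sigma))
    shift = float(np.hypot(cur.x - orig.x, cur.y - orig.y))
    if shift > params.max_shift_mult * orig.radius:
        return None
    if not (params.r_min_um <= cur.radius <= params.r_max_um):
        return None
    return cur
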