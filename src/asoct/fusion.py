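"""Dual-reference-arm frame registration and SNR-normalizing fusion.

Arm 1 images the anterior segment with its zero-delay plane (highest SNR)
at the top; arm 2 with it at the bottom.  After axially flipping the arm-2
frame into anatomical orientation, the two frames share a common central
band (iris and anterior lens) which drives a rigid registration (rotation +
translation, normalized cross-correlation).  The frames are then blended on
an extended depth grid with per-depth weights proportional to each arm's
modeled linear-scale sensitivity, so the low-SNR half of each frame is
carried by the other arm and the sensitivity drop-off over the full depth
range shrinks from the single-arm value to the value at mid-depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.transform import rotate as sk_rotate

from .errors import DomainError, GeometryError, MisuseError, RegistrationError
from .simulator import ArmGeometry


@dataclass
class BScanFrame:
    """One reconstructed log-intensity raster (depth x lateral, dB)."""

    raster: np.ndarray
    arm_id: int
    zero_delay_placement: str  # "top" | "bottom"
    depth_per_pixel: float  # mm
    lateral_per_pixel: float  # mm

    def __post_init__(self):
        if self.zero_delay_placement not in ("top", "bottom"):
            raise DomainError("zero_delay_placement must be 'top' or 'bottom'")

    @property
    def n_depth(self) -> int:
        return self.raster.shape[0]

    @property
    def n_alines(self) -> int:
        return self.raster.shape[1]


@dataclass(frozen=True)
class RigidTransform:
    """Estimated rigid misalignment of the oriented arm-2 frame.

    ``rotation`` (degrees, about the frame center) is the rotation the
    arm-2 content carries relative to frame 1; it is undone by rotating the
    frame by ``-rotation``.  ``translation`` = (axial px, lateral px) is the
    offset to add to the nominal placement so that the de-rotated content
    aligns with the frame-1 anatomy (content shifted down by +7 rows
    registers as dz = -7: it must be placed 7 rows higher).
    """

    rotation: float
    translation: tuple[float, float]
    correlation: float = float("nan")

    def __post_init__(self):
        if abs(self.rotation) > 10.0:
            raise DomainError("|rotation| must be <= 10 degrees")
        if not all(map(math.isfinite, self.translation)):
            raise DomainError("translation must be finite")


@dataclass
class FusedImage:
    """Registered, overlapped dual-arm image with its sensitivity model."""

    raster: np.ndarray  # (depth, lateral), dB
    depth_per_pixel: float
    lateral_per_pixel: float
    transform: RigidTransform
    sensitivity_profile: np.ndarray  # dB vs depth bin (model)
    combined_dropoff_db: float
    arm2_zero_depth: float  # mm, depth of arm 2's zero-delay plane

    @property
    def depth_axis(self) -> np.ndarray:
        return np.arange(self.raster.shape[0]) * self.depth_per_pixel

    @property
    def lateral_axis(self) -> np.ndarray:
        n = self.raster.shape[1]
        return (np.arange(n) - (n - 1) / 2.0) * self.lateral_per_pixel


def orient_arm2(frame: BScanFrame) -> BScanFrame:
    """Axially flip the arm-2 frame into anatomical (cornea-up) orientation."""
    if frame.arm_id != 2:
        raise MisuseError(f"orient_arm2 expects the arm-2 frame, got arm {frame.arm_id}")
    placement = "bottom" if frame.zero_delay_placement == "top" else "top"
    return replace(frame, raster=frame.raster[::-1].copy(), zero_delay_placement=placement)


def nominal_row_offset(arm_geometry: ArmGeometry, depth_per_pixel: float, n_depth: int) -> int:
    """Row in the arm-1/fused grid where the oriented arm-2 frame's first row
    nominally lands (can be negative: that part is above the fused grid)."""
    return int(round(arm_geometry.opd_offset / depth_per_pixel)) - (n_depth - 1)


def single_arm_sensitivity_linear(depth_mm, z_max: float):
    """Modeled linear-power sensitivity vs distance from the zero-delay plane.

    The boxcar pixel integration attenuates the fringe amplitude by
    sinc(z / (2 z_max)) (numpy convention), hence the power envelope is its
    square.  Clipped at a small floor so blend weights stay finite.
    """
    d = np.abs(np.asarray(depth_mm, dtype=float))
    env = np.sinc(d / (2.0 * z_max)) ** 2
    return np.clip(env, 1e-12, None)


def _template_band(img: np.ndarray, nominal, search, n_rows1, band_halfwidth_px):
    """Row band of ``img`` richest in structure that maps into frame 1.

    Centered on the strongest row (in the anterior segment that is the iris
    plane / anterior lens, the features shared by both arms).
    """
    lo_limit = max(0, -nominal + search + 1)
    hi_limit = min(img.shape[0], n_rows1 - nominal - search - 1)
    if hi_limit - lo_limit < 16:
        return None
    floor = np.median(img)
    strength = img[lo_limit:hi_limit].max(axis=1) - floor
    center = lo_limit + int(np.argmax(strength))
    r_lo = max(lo_limit, center - band_halfwidth_px)
    r_hi = min(hi_limit, center + band_halfwidth_px)
    if r_hi - r_lo < 16:
        return None
    return r_lo, r_hi


def _ncc_in_band(f1, img2, band, nominal, search, decimate=1):
    """Best NCC and offsets for an already-rotated arm-2 raster.  Returns
    (correlation, dz, dx) with offsets relative to nominal placement."""
    r_lo, r_hi = band
    ncols = img2.shape[1]
    c_lo, c_hi = search + 1, ncols - search - 1
    if c_hi - c_lo < 16:
        return -1.0, 0.0, 0.0
    template = img2[r_lo:r_hi:decimate, c_lo:c_hi:decimate]
    sr_lo = r_lo + nominal - search
    sr_hi = r_hi + nominal + search
    region = f1[sr_lo:sr_hi:decimate, c_lo - search : c_hi + search : decimate]
    if region.shape[0] <= template.shape[0] or region.shape[1] <= template.shape[1]:
        return -1.0, 0.0, 0.0
    ncc = match_template(region, template)
    j = np.unravel_index(np.argmax(ncc), ncc.shape)
    peak = float(ncc[j])
    dz = (j[0] + _parabolic_offset(ncc[:, j[1]], j[0])) * decimate - search
    dx = (j[1] + _parabolic_offset(ncc[j[0], :], j[1])) * decimate - search
    return peak, float(dz), float(dx)


def _parabolic_offset(v, j):
    if 0 < j < v.size - 1:
        denom = v[j - 1] - 2.0 * v[j] + v[j + 1]
        if denom < 0:
            return float(np.clip(0.5 * (v[j - 1] - v[j + 1]) / denom, -0.5, 0.5))
    return 0.0


def register_frames(
    frame1: BScanFrame,
    oriented_frame2: BScanFrame,
    nominal_offset_px: int,
    search_px: int = 30,
    rotation_span: float = 3.0,
    rotation_step: float = 1.0,
    min_correlation: float = 0.2,
    band_halfwidth_mm: float = 1.0,
    decimate: int = 2,
) -> RigidTransform:
    """Estimate the rigid transform between the overlap regions.

    The template is the structure-richest band of the oriented arm-2 frame
    (the iris plane and anterior lens, the features both arms share).
    Normalized cross-correlation locates it in frame 1 within
    +-``search_px`` of the nominal offset; rotation is searched on a coarse
    grid over +-``rotation_span`` degrees (decimated by ``decimate`` for
    speed) and refined by bisection, with a final full-resolution pass.
    Pass ``rotation_span=0`` to search translation only.

    Raises
    ------
    RegistrationError
        If the best correlation stays below ``min_correlation``.
    """
    f1 = frame1.raster.astype(float)
    f2 = oriented_frame2.raster.astype(float)
    cval = float(np.median(f2))
    band_px = max(16, int(round(band_halfwidth_mm / frame1.depth_per_pixel)))
    band = _template_band(f2, nominal_offset_px, search_px, f1.shape[0], band_px)
    if band is None:
        raise RegistrationError("overlap region too small for registration")

    results = {}

    def evaluate(theta, dec):
        theta = float(np.clip(theta, -10.0, 10.0))
        key = (round(theta, 4), dec)
        if key not in results:
            img2 = f2 if theta == 0.0 else sk_rotate(f2, -theta, preserve_range=True, cval=cval)
            results[key] = _ncc_in_band(f1, img2, band, nominal_offset_px, search_px, dec)
        return results[key][0]

    if rotation_span > 0:
        grid = list(np.arange(-rotation_span, rotation_span + rotation_step / 2, rotation_step))
    else:
        grid = [0.0]
    scores = [evaluate(t, decimate) for t in grid]
    best_theta = float(grid[int(np.argmax(scores))])
    if len(grid) > 1:
        # refine by the differential axial shift of the band's two halves:
        # maximizing correlation over the angle is biased toward nonzero
        # angles because interpolation blur slightly inflates the NCC
        for _ in range(2):
            img2 = (
                f2 if best_theta == 0.0
                else sk_rotate(f2, -best_theta, preserve_range=True, cval=cval)
            )
            resid = _split_band_rotation(f1, img2, band, nominal_offset_px, search_px)
            if not math.isfinite(resid) or abs(resid) < 0.005:
                break
            best_theta = float(np.clip(best_theta + resid, -10.0, 10.0))
    corr, dz, dx = _final_eval(f1, f2, best_theta, band, nominal_offset_px, search_px, cval)
    if corr < min_correlation:
        raise RegistrationError(
            f"registration failed: best correlation {corr:.3f} < {min_correlation}"
        )
    return RigidTransform(rotation=float(best_theta), translation=(dz, dx), correlation=corr)


def _final_eval(f1, f2, theta, band, nominal, search, cval):
    img2 = f2 if theta == 0.0 else sk_rotate(f2, -theta, preserve_range=True, cval=cval)
    return _ncc_in_band(f1, img2, band, nominal, search, 1)


def _split_band_rotation(f1, img2, band, nominal, search):
    """Residual rotation from the differential axial shift of the left and
    right halves of the template band (degrees); NaN if either half fails.

    Unlike correlation-vs-angle maximization this is immune to the slight
    correlation inflation that interpolation blur produces at nonzero
    angles.
    """
    r_lo, r_hi = band
    ncols = img2.shape[1]
    mid = ncols // 2
    c_margin = search + 1
    if mid - c_margin < 16 or ncols - c_margin - mid < 16:
        return math.nan
    shifts, centers = [], []
    for c0, c1 in ((c_margin, mid), (mid, ncols - c_margin)):
        template = img2[r_lo:r_hi, c0:c1]
        region = f1[r_lo + nominal - search : r_hi + nominal + search, c0 - search : c1 + search]
        if region.shape[0] <= template.shape[0] or region.shape[1] <= template.shape[1]:
            return math.nan
        ncc = match_template(region, template)
        j = np.unravel_index(np.argmax(ncc), ncc.shape)
        if ncc[j] < 0.05:
            return math.nan
        shifts.append(j[0] + _parabolic_offset(ncc[:, j[1]], j[0]) - search)
        centers.append((c0 + c1) / 2.0)
    return math.degrees(math.atan2(shifts[1] - shifts[0], centers[1] - centers[0]))


def overlap_frames(
    frame1: BScanFrame,
    oriented_frame2: BScanFrame,
    transform: RigidTransform,
    arm_geometry: ArmGeometry | None = None,
    nominal_offset_px: int | None = None,
    sensitivity_model=None,
    z_max: float | None = None,
) -> FusedImage:
    """Blend the registered frames into one full-depth image.

    The arm-2 raster is resampled by the estimated transform onto arm 1's
    grid extended to the full anatomical depth.  Per-depth blend weights are
    proportional to each arm's modeled linear-power sensitivity at that
    depth (they sum to 1 where both frames contribute; single-arm regions
    take weight 1).  The reported ``sensitivity_profile`` is the per-depth
    best-arm (max-combined) model in dB, and ``combined_dropoff_db`` is its
    max-minus-min over the anatomically covered range, i.e. down to arm 2's
    zero-delay plane.

    ``sensitivity_model`` maps distance-from-zero-delay (mm) to linear
    power; the default is the pixel-integration sinc^2 envelope.
    """
    dpp = frame1.depth_per_pixel
    m = frame1.n_depth
    if nominal_offset_px is None:
        if arm_geometry is None:
            raise DomainError("need arm_geometry or nominal_offset_px")
        nominal_offset_px = nominal_row_offset(arm_geometry, dpp, m)
    z_max = z_max if z_max is not None else m * dpp
    if sensitivity_model is None:
        sensitivity_model = lambda d: single_arm_sensitivity_linear(d, z_max)  # noqa: E731

    dz, dx = transform.translation
    r0 = nominal_offset_px + dz  # fused row of arm-2's first row
    z2_zero = (r0 + m - 1) * dpp  # fused depth of arm 2's zero-delay plane
    n_out = max(m, int(math.ceil(r0 + m)))
    if r0 >= n_out or r0 + m <= 0:
        raise GeometryError("transform places the arm-2 frame outside the fused raster")

    floor = float(np.min(oriented_frame2.raster))
    img2 = oriented_frame2.raster.astype(float)
    if transform.rotation != 0.0:
        img2 = sk_rotate(img2, -transform.rotation, preserve_range=True, cval=floor)
    canvas2 = np.full((n_out, frame1.n_alines), floor)
    # content col c shows anatomy that arm 1 sees at col c + dx, row j at
    # fused row r0 + j; shift by the fractional row part and the lateral offset
    shifted = ndimage.shift(
        img2, (r0 - math.floor(r0), dx), order=1, mode="constant", cval=floor
    )
    lo = int(math.floor(r0))
    src_lo = max(0, -lo)
    dst_lo = max(0, lo)
    length = min(m - src_lo, n_out - dst_lo)
    canvas2[dst_lo : dst_lo + length] = shifted[src_lo : src_lo + length]
    valid2 = np.zeros(n_out, dtype=bool)
    valid2[dst_lo : dst_lo + length] = True

    depths = np.arange(n_out) * dpp
    s1 = np.asarray(sensitivity_model(depths), dtype=float)
    s2 = np.asarray(sensitivity_model(np.abs(z2_zero - depths)), dtype=float)
    w1 = np.where(depths <= (m - 1) * dpp, s1, 0.0)
    w2 = np.where(valid2, s2, 0.0)
    wsum = w1 + w2

    lin1 = np.zeros((n_out, frame1.n_alines))
    lin1[:m] = 10.0 ** (frame1.raster / 10.0)
    lin2 = 10.0 ** (canvas2 / 10.0)
    lin_floor = 10.0 ** (floor / 10.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fused_lin = (w1[:, None] * lin1 + w2[:, None] * lin2) / wsum[:, None]
    fused_lin[wsum == 0] = lin_floor
    fused_db = 10.0 * np.log10(np.clip(fused_lin, lin_floor, None))

    combined = np.maximum(s1, np.asarray(sensitivity_model(np.abs(z2_zero - depths))))
    profile_db = 10.0 * np.log10(combined)
    anat = depths <= min(z2_zero, depths[-1]) + 1e-9
    dropoff = float(profile_db[anat].max() - profile_db[anat].min())

    return FusedImage(
        raster=fused_db,
        depth_per_pixel=dpp,
        lateral_per_pixel=frame1.lateral_per_pixel,
        transform=transform,
        sensitivity_profile=profile_db,
        combined_dropoff_db=dropoff,
        arm2_zero_depth=z2_zero,
    )


def fuse_pair(
    frame1: BScanFrame,
    frame2: BScanFrame,
    arm_geometry: ArmGeometry,
    z_max: float | None = None,
    **register_kwargs,
) -> FusedImage:
    """Orient, register and overlap a raw reconstructed frame pair."""
    oriented = orient_arm2(frame2)
    r0 = nominal_row_offset(arm_geometry, frame1.depth_per_pixel, frame1.n_depth)
    transform = register_frames(frame1, oriented, r0, **register_kwargs)
    return overlap_frames(
        frame1, oriented, transform, nominal_offset_px=r0, z_max=z_max
    )
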