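"""Anterior-segment biometry from fused OCT images.

The measurement chain mirrors the bench analysis of a combined dual-arm
image: longitudinal reflectivity profiles (excluding the central A-scans
corrupted by the specular apex reflex) locate the principal boundary peaks;
per-A-line peak following traces each boundary in optical-path coordinates;
a layer-by-layer Snell-law correction with the 840 nm refractive indices
(cornea 1.387, aqueous 1.342, lens 1.408) converts the traces to geometric
coordinates; circle fits yield the four curvature radii and apex distances
yield CCT, ACD (posterior cornea to anterior lens) and CLT.  Dynamic series
of these quantities under an accommodative step are summarized by logistic
(sigmoid) fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .errors import (
    DomainError,
    IncompleteSegmentationError,
    FitError,
    TracingError,
)
from .phantom import (
    CORNEA_ANTERIOR,
    CORNEA_POSTERIOR,
    LENS_ANTERIOR,
    LENS_POSTERIOR,
    ORDERED_SURFACES,
    BiometryResult,
    MediaStack,
    SigmoidParams,
)

# ---------------------------------------------------------------------------
# Reflectivity profiles and peak labeling
# ---------------------------------------------------------------------------


@dataclass
class ReflectivityProfile:
    """Averaged longitudinal reflectivity profile (dB vs optical depth)."""

    depths: np.ndarray  # mm
    values: np.ndarray  # dB
    strip_columns: tuple = ()  # which A-scan columns were averaged
    peaks: list = field(default_factory=list)  # (depth mm, label)


@dataclass
class LabeledPeaks:
    """Principal anatomical peaks plus any corneal sub-peaks."""

    principal: dict  # label -> depth mm
    sub_peaks: list  # (label, depth mm), e.g. Bowman's-layer boundaries
    all_peaks: np.ndarray  # depths of every detected peak, mm


def axial_profile(image, strip_halfwidth_alines: int = 50, exclude_halfwidth: int = 25):
    """Longitudinal reflectivity profile flanking the excluded central band.

    The central ``2 * exclude_halfwidth`` A-scans (the specular-reflex
    stripe) are excluded; the ``strip_halfwidth_alines`` A-scans on either
    side are averaged on the linear-power scale and returned in dB.

    ``image`` is any object with ``raster`` (depth x lateral, dB) and
    ``depth_per_pixel`` attributes.
    """
    raster = image.raster
    n_cols = raster.shape[1]
    need = 2 * exclude_halfwidth + 2 * strip_halfwidth_alines
    if n_cols <= need:
        raise DomainError(f"image has {n_cols} A-scans; needs more than {need}")
    c = n_cols // 2
    left = slice(c - exclude_halfwidth - strip_halfwidth_alines, c - exclude_halfwidth)
    right = slice(c + exclude_halfwidth, c + exclude_halfwidth + strip_halfwidth_alines)
    cols = np.r_[np.arange(n_cols)[left], np.arange(n_cols)[right]]
    linear = 10.0 ** (raster[:, cols] / 10.0)
    values = 10.0 * np.log10(linear.mean(axis=1))
    depths = np.arange(raster.shape[0]) * image.depth_per_pixel
    return ReflectivityProfile(depths=depths, values=values, strip_columns=tuple(cols))


def detect_boundary_peaks(
    profile: ReflectivityProfile,
    min_prominence_db: float = 6.0,
    min_separation: float = 0.3,
    sub_peak_window: float = 0.15,
    exclude_dc: float = 0.15,
) -> LabeledPeaks:
    """Label the profile's peaks with their anatomical boundaries.

    Local maxima with >= ``min_prominence_db`` prominence are grouped into
    clusters separated by at least ``min_separation`` mm; the four most
    prominent clusters, in depth order, are the anterior/posterior cornea
    and anterior/posterior lens.  Extra peaks within ``sub_peak_window`` mm
    of the corneal surface (Bowman's-layer boundaries) are reported as
    sub-peaks when the axial resolution separates them.

    Raises
    ------
    IncompleteSegmentationError
        If fewer than four principal clusters are found (lists the labels
        that could be assigned).
    """
    v = profile.values
    d = profile.depths
    start = int(np.searchsorted(d, exclude_dc))
    idx, props = signal.find_peaks(v[start:], prominence=min_prominence_db)
    idx = idx + start
    if idx.size == 0:
        raise IncompleteSegmentationError([], "no peaks found")
    depths = d[idx]
    prom = props["prominences"]

    # cluster peaks closer than min_separation
    order = np.argsort(depths)
    clusters = [[order[0]]]
    for i in order[1:]:
        if depths[i] - depths[clusters[-1][-1]] < min_separation:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    cluster_depth = [depths[max(c, key=lambda j: v[idx[j]])] for c in clusters]
    cluster_prom = [max(prom[j] for j in c) for c in clusters]

    if len(clusters) < 4:
        found = [ORDERED_SURFACES[i] for i in range(len(clusters))]
        raise IncompleteSegmentationError(found, f"only {len(clusters)} principal peaks")
    keep = sorted(np.argsort(cluster_prom)[-4:])
    principal = {
        label: float(cluster_depth[ci]) for label, ci in zip(ORDERED_SURFACES, keep)
    }

    sub = []
    ca = principal[CORNEA_ANTERIOR]
    extra = [float(x) for x in depths if abs(x - ca) <= sub_peak_window]
    if len(extra) >= 2:
        for n, x in enumerate(sorted(extra)):
            sub.append((f"bowman-{'ab'[min(n, 1)]}" if n < 2 else "cornea-sub", x))
    profile.peaks = [(v, k) for k, v in principal.items()] + [(x, l) for l, x in sub]
    return LabeledPeaks(principal=principal, sub_peaks=sub, all_peaks=np.sort(depths))


# ---------------------------------------------------------------------------
# Boundary tracing
# ---------------------------------------------------------------------------

SOURCE_AUTO = 1
SOURCE_INTERP = 2
SOURCE_MANUAL = 3


@dataclass
class BoundaryTrace:
    """Per-interface boundary samples in optical-path coordinates."""

    label: str
    lateral: np.ndarray  # mm
    depth: np.ndarray  # optical-path mm, NaN outside the traced aperture
    source: np.ndarray  # SOURCE_* flags per column (0 = absent)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.depth)


def _parabolic_peak(y, j):
    if 0 < j < y.size - 1:
        denom = y[j - 1] - 2.0 * y[j] + y[j + 1]
        if denom < 0:
            d = 0.5 * (y[j - 1] - y[j + 1]) / denom
            return j + d
    return float(j)


def trace_boundaries(
    image,
    seeds: dict | None = None,
    exclude_halfwidth: int = 25,
    strip_halfwidth_alines: int = 50,
    min_prominence_db: float = 6.0,
    max_jump_px: float = 3.0,
    max_gap: int = 12,
    min_coverage: float = 0.6,
    manual_overrides=None,
) -> dict[str, BoundaryTrace]:
    """Trace each anatomical boundary across the B-scan by peak following.

    Starting from the apex depths found in the flanking reflectivity
    profiles, the tracer marches outward column by column, accepting the
    local intensity maximum within ``max_jump_px`` depth pixels of its
    neighbor when it rises ``min_prominence_db`` above the column's median
    floor.  Rejected columns count as gaps; after ``max_gap`` consecutive
    gaps the surface is considered ended (e.g. the lens surfaces at the
    pupil margin).  Accepted samples are median-filtered with outlier
    rejection, interior gaps are interpolated, and manual override points
    ``(label, x_mm, depth_mm)`` are honored exactly.

    Raises
    ------
    TracingError
        If a surface is detected on fewer than ``min_coverage`` of the
        columns between its traced end points.
    """
    raster = image.raster
    dpp = image.depth_per_pixel
    n_depth, n_cols = raster.shape
    lateral = image.lateral_axis if hasattr(image, "lateral_axis") else (
        (np.arange(n_cols) - (n_cols - 1) / 2.0) * image.lateral_per_pixel
    )
    lateral = np.asarray(lateral)

    if seeds is None:
        profile = axial_profile(
            image, strip_halfwidth_alines=strip_halfwidth_alines,
            exclude_halfwidth=exclude_halfwidth,
        )
        seeds = detect_boundary_peaks(profile, min_prominence_db).principal

    col_floor = np.median(raster, axis=0)
    c = n_cols // 2
    band = (c - exclude_halfwidth, c + exclude_halfwidth)  # [lo, hi) excluded
    half_win = int(max_jump_px) + 2

    traces = {}
    for label, d0 in seeds.items():
        depth_px = np.full(n_cols, np.nan)
        src = np.zeros(n_cols, dtype=np.uint8)
        for side in (+1, -1):
            cols = range(band[1], n_cols) if side > 0 else range(band[0] - 1, -1, -1)
            prev = d0 / dpp
            gaps = 0
            for col in cols:
                lo = max(0, int(round(prev)) - half_win)
                hi = min(n_depth, int(round(prev)) + half_win + 1)
                seg = raster[lo:hi, col]
                j = int(np.argmax(seg))
                pos = lo + _parabolic_peak(seg, j)
                ok = (
                    seg[j] - col_floor[col] >= min_prominence_db
                    and abs(pos - prev) <= max_jump_px + 0.5
                )
                if ok:
                    depth_px[col] = pos
                    src[col] = SOURCE_AUTO
                    prev = pos
                    gaps = 0
                else:
                    gaps += 1
                    if gaps > max_gap:
                        break
        depth_px = _clean_trace(depth_px, max_jump_px)
        src[~np.isfinite(depth_px) & (src == SOURCE_AUTO)] = 0

        valid = np.nonzero(np.isfinite(depth_px))[0]
        if valid.size:
            span = np.arange(valid[0], valid[-1] + 1)
            in_band = (span >= band[0]) & (span < band[1])
            coverage = np.isfinite(depth_px[span]).sum() / max(1, (~in_band).sum())
            if coverage < min_coverage:
                raise TracingError(label, coverage)
            gaps_idx = span[~np.isfinite(depth_px[span])]
            depth_px[gaps_idx] = np.interp(gaps_idx, valid, depth_px[valid])
            src[gaps_idx] = SOURCE_INTERP
        else:
            raise TracingError(label, 0.0)

        traces[label] = BoundaryTrace(
            label=label, lateral=lateral, depth=depth_px * dpp, source=src
        )

    for label, x_mm, depth_mm in manual_overrides or []:
        tr = traces[label]
        col = int(np.argmin(np.abs(lateral - x_mm)))
        tr.depth[col] = depth_mm
        tr.source[col] = SOURCE_MANUAL
    return traces


def _clean_trace(depth_px, max_jump_px, size=5):
    """Median filter with outlier rejection, NaN-aware."""
    out = depth_px.copy()
    valid = np.nonzero(np.isfinite(out))[0]
    if valid.size < size:
        return out
    series = out[valid]
    med = signal.medfilt(series, kernel_size=size)
    bad = np.abs(series - med) > max_jump_px
    series[bad] = np.nan
    out[valid] = series
    return out


# ---------------------------------------------------------------------------
# Circle fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle: signed radius (mm) and center (lateral, axial)."""

    radius: float  # signed; +inf for a flat (collinear) point set
    center: tuple[float, float]
    rms: float = 0.0

    @property
    def is_flat(self) -> bool:
        return not math.isfinite(self.radius)


def fit_circle(x, z, refine: bool = True, robust: bool = False) -> CircleFit:
    """Fit a circle to points in the meridian plane.

    Algebraic (Kasa) least squares provides the initial estimate, refined by
    geometric least squares.  With ``robust=True`` samples whose residual
    exceeds 3 robust standard deviations are rejected and the fit repeated
    (stray tracer samples at a surface's edge act on a long lever arm).
    Collinear points return a flat sentinel (infinite radius).  The sign of
    the radius is positive when the center of curvature lies posterior
    (deeper) than the surface, matching the phantom's convention.

    Raises
    ------
    DomainError
        If fewer than 3 points are supplied.
    """
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    m = np.isfinite(x) & np.isfinite(z)
    x, z = x[m], z[m]
    if x.size < 3:
        raise DomainError("circle fit needs at least 3 points")

    # exactly collinear samples make the algebraic system singular in a way
    # that rounding can turn into an arbitrary huge-but-finite radius
    span = max(x.max() - x.min(), z.max() - z.min(), 1e-12)
    if _line_rms(x, z) < 1e-8 * span:
        return CircleFit(math.inf, (math.nan, math.nan), rms=_line_rms(x, z))

    a = np.column_stack([2.0 * x, 2.0 * z, np.ones_like(x)])
    b = x * x + z * z
    try:
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    except np.linalg.LinAlgError:
        return CircleFit(math.inf, (math.nan, math.nan))
    cx, cz, c0 = sol
    r2 = c0 + cx * cx + cz * cz
    if r2 <= 0 or math.sqrt(r2) >= 1.0e5:
        return CircleFit(math.inf, (math.nan, math.nan), rms=_line_rms(x, z))

    def residuals(p):
        return np.hypot(x - p[0], z - p[1]) - p[2]

    p0 = np.array([cx, cz, math.sqrt(r2)])
    if refine:
        res = optimize.least_squares(residuals, p0, method="lm", max_nfev=200)
        p0 = res.x
    if robust and refine:
        for _ in range(2):
            resid = residuals(p0)
            mad = np.median(np.abs(resid - np.median(resid)))
            keep = np.abs(resid) <= max(3.0 * 1.4826 * mad, 1e-5)
            if keep.all() or keep.sum() < 3:
                break
            x, z = x[keep], z[keep]

            def residuals(p):  # noqa: F811 - rebound over the kept samples
                return np.hypot(x - p[0], z - p[1]) - p[2]

            p0 = optimize.least_squares(residuals, p0, method="lm", max_nfev=200).x
    cx, cz, r = p0
    if r >= 1.0e5:
        return CircleFit(math.inf, (math.nan, math.nan), rms=_line_rms(x, z))
    z_apex = z[np.argmin(np.abs(x))]
    sign = 1.0 if cz >= z_apex else -1.0
    rms = float(np.sqrt(np.mean(residuals((cx, cz, r)) ** 2)))
    return CircleFit(float(sign * r), (float(cx), float(cz)), rms=rms)


def _line_rms(x, z):
    coef = np.polyfit(x, z, 1)
    return float(np.sqrt(np.mean((z - np.polyval(coef, x)) ** 2)))


# ---------------------------------------------------------------------------
# Refraction correction
# ---------------------------------------------------------------------------


def refraction_correct(
    traces: dict[str, BoundaryTrace],
    media: MediaStack | None = None,
    fit_apertures: dict | None = None,
) -> dict[str, np.ndarray]:
    """Convert optical-path boundary traces to geometric coordinates.

    Layer-by-layer ray tracing: every A-line enters the eye vertically; at
    each corrected interface the local normal comes from a circle fitted to
    that interface's already-corrected trace, the ray refracts by Snell's
    law (n1 sin t1 = n2 sin t2), and each deeper sample is reached by
    propagating a geometric distance (optical-path increment) / n along the
    refracted ray.  This inverts the forward image-formation model exactly.

    Returns a dict label -> (2, n) array of (lateral, axial) geometric
    coordinates; the axial origin is the same as the input traces' (the
    corneal surface stays where the optical trace put it, as it is reached
    through air).

    Raises
    ------
    DomainError
        On total internal reflection (impossible at these indices for
        near-normal incidence).
    OrderingError-like GeometryError is not raised here; unordered traces
    surface as negative optical increments and raise ``DomainError``.
    """
    media = media or MediaStack()
    fit_apertures = fit_apertures or {}
    for label in ORDERED_SURFACES:
        if label not in traces:
            raise IncompleteSegmentationError(list(traces), f"missing trace {label!r}")

    x = traces[CORNEA_ANTERIOR].lateral
    d = {lbl: traces[lbl].depth for lbl in ORDERED_SURFACES}
    n_seq = media.ordered_indices() + (media.n_aqueous,)

    p_lat = x.astype(float).copy()
    p_z = d[CORNEA_ANTERIOR].astype(float).copy()  # air: optical = geometric
    u_lat = np.zeros_like(p_lat)
    u_z = np.ones_like(p_lat)
    corrected = {CORNEA_ANTERIOR: np.vstack([p_lat, p_z])}

    for i, label in enumerate(ORDERED_SURFACES[1:], start=1):
        prev_label = ORDERED_SURFACES[i - 1]
        n1, n2 = n_seq[i - 1], n_seq[i]
        u_lat, u_z = _refract_at_surface(
            corrected[prev_label], p_lat, p_z, u_lat, u_z, n1, n2,
            fit_apertures.get(prev_label),
        )
        delta = d[label] - d[prev_label]
        if np.any(delta[np.isfinite(delta)] < 0):
            raise DomainError(f"optical path decreases from {prev_label} to {label}")
        step = delta / n2
        p_lat = p_lat + step * u_lat
        p_z = p_z + step * u_z
        corrected[label] = np.vstack([p_lat, p_z])
    return corrected


def _refract_at_surface(surface_pts, p_lat, p_z, u_lat, u_z, n1, n2, aperture):
    if n1 == n2:
        return u_lat, u_z
    xs, zs = surface_pts
    m = np.isfinite(xs) & np.isfinite(zs)
    if aperture is not None:
        m &= np.abs(xs) <= aperture
    circ = fit_circle(xs[m], zs[m])
    if circ.is_flat:
        n_lat = np.zeros_like(p_lat)
        n_z = -np.ones_like(p_z)
    else:
        cx, cz = circ.center
        r = abs(circ.radius)
        n_lat = (p_lat - cx) / r
        n_z = (p_z - cz) / r
        flip = (n_lat * u_lat + n_z * u_z) > 0
        n_lat = np.where(flip, -n_lat, n_lat)
        n_z = np.where(flip, -n_z, n_z)
    r12 = n1 / n2
    cos1 = -(u_lat * n_lat + u_z * n_z)
    sin2sq = r12 * r12 * (1.0 - cos1 * cos1)
    if np.any(sin2sq[np.isfinite(sin2sq)] > 1.0):
        raise DomainError("total internal reflection during correction")
    cos2 = np.sqrt(np.clip(1.0 - sin2sq, 0.0, None))
    f = r12 * cos1 - cos2
    return r12 * u_lat + f * n_lat, r12 * u_z + f * n_z


# ---------------------------------------------------------------------------
# Biometry extraction
# ---------------------------------------------------------------------------

#: Default lateral half-widths (mm) over which each surface's circle is fitted.
DEFAULT_FIT_APERTURES = {
    CORNEA_ANTERIOR: 3.0,
    CORNEA_POSTERIOR: 3.0,
    LENS_ANTERIOR: None,  # pupil-limited; use all traced samples
    LENS_POSTERIOR: None,
}


def _apex_depth(x, z, halfwidth=1.5, exclude=None):
    """Apex (x = 0) depth by quadratic fit from both flanks."""
    m = np.isfinite(z) & (np.abs(x) <= halfwidth)
    if exclude is not None:
        m &= ~exclude
    if m.sum() < 6:
        raise DomainError("too few samples for apex interpolation")
    coef = np.polyfit(x[m], z[m], 2)
    return float(np.polyval(coef, 0.0))


def compute_biometry(
    corrected: dict[str, np.ndarray],
    meridian: str = "horizontal",
    state: str = "relaxed",
    fit_apertures: dict | None = None,
    apex_halfwidth: float = 1.5,
    apex_exclude: dict | None = None,
    fit_masks: dict | None = None,
) -> BiometryResult:
    """Axial distances and curvature radii from corrected boundary traces.

    CCT/ACD/CLT are differences of apex depths obtained by quadratic
    interpolation across the excluded central band; the four radii come
    from circle fits over each surface's fit aperture (full cornea, pupil-
    limited lens).  Radii are reported as magnitudes.  ``fit_masks`` (per
    label) restricts fits to trustworthy samples, e.g. excluding gap-
    interpolated columns whose chords would bias the curvature.

    Raises
    ------
    IncompleteSegmentationError
        If any of the four boundary traces is missing.
    """
    apertures = dict(DEFAULT_FIT_APERTURES)
    if fit_apertures:
        apertures.update(fit_apertures)
    for label in ORDERED_SURFACES:
        if label not in corrected:
            raise IncompleteSegmentationError(list(corrected), f"missing {label!r}")

    apex = {}
    radii = {}
    for label in ORDERED_SURFACES:
        xs, zs = corrected[label]
        good = np.isfinite(zs)
        if fit_masks and label in fit_masks:
            good &= fit_masks[label]
        excl = (apex_exclude or {}).get(label)
        apex[label] = _apex_depth(xs, np.where(good, zs, np.nan), apex_halfwidth, excl)
        ap = apertures.get(label)
        m = good if ap is None else (good & (np.abs(xs) <= ap))
        circ = fit_circle(xs[m], zs[m], robust=True)
        radii[label] = abs(circ.radius)

    return BiometryResult(
        cct=apex[CORNEA_POSTERIOR] - apex[CORNEA_ANTERIOR],
        acd=apex[LENS_ANTERIOR] - apex[CORNEA_POSTERIOR],
        clt=apex[LENS_POSTERIOR] - apex[LENS_ANTERIOR],
        rac=radii[CORNEA_ANTERIOR],
        rpc=radii[CORNEA_POSTERIOR],
        ral=radii[LENS_ANTERIOR],
        rpl=radii[LENS_POSTERIOR],
        meridian=meridian,
        state=state,
    )


def biometry_from_fused(
    fused,
    media: MediaStack | None = None,
    meridian: str = "horizontal",
    state: str = "relaxed",
    exclude_halfwidth: int | None = None,
    **trace_kwargs,
):
    """Full measurement chain on a fused image.

    The excluded central band and the flanking profile strips default to
    the protocol widths of a 1024-A-line scan (band of 50, strips of 50),
    scaled to the image's actual lateral sampling.

    Returns ``(result, traces, corrected)``.
    """
    n_total = fused.raster.shape[1]
    if exclude_halfwidth is None:
        exclude_halfwidth = max(4, round(25 * n_total / 1024))
    trace_kwargs.setdefault("strip_halfwidth_alines", max(12, round(50 * n_total / 1024)))
    traces = trace_boundaries(fused, exclude_halfwidth=exclude_halfwidth, **trace_kwargs)
    surface_traces = {k: v for k, v in traces.items() if k in ORDERED_SURFACES}
    corrected = refraction_correct(surface_traces, media)
    n_cols = fused.raster.shape[1]
    c = n_cols // 2
    in_band = np.zeros(n_cols, dtype=bool)
    in_band[c - exclude_halfwidth : c + exclude_halfwidth] = True
    fit_masks = {
        lbl: np.isin(surface_traces[lbl].source, (SOURCE_AUTO, SOURCE_MANUAL))
        for lbl in ORDERED_SURFACES
    }
    result = compute_biometry(
        corrected,
        meridian=meridian,
        state=state,
        apex_exclude={lbl: in_band for lbl in ORDERED_SURFACES},
        fit_masks=fit_masks,
    )
    return result, traces, corrected


# ---------------------------------------------------------------------------
# Sigmoid dynamics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted logistic time course and its residual RMS."""

    baseline: float
    amplitude: float
    t0: float
    k: float
    residual_rms: float

    def value(self, t):
        return SigmoidParams(self.baseline, self.amplitude, self.t0, self.k).value(t)


def fit_sigmoid(t, y, n_restarts: int = 5, seed: int = 0) -> SigmoidFit:
    """Nonlinear least-squares fit of y(t) = b + a / (1 + exp(-k (t - t0))).

    Initialization: baseline from the first-quartile mean, amplitude from
    the last-minus-first-quartile means, t0 at the steepest smoothed slope,
    k from the 10-90% rise time; five jittered restarts guard against local
    minima.  A constant series returns amplitude 0 and the series mean.

    Raises
    ------
    FitError
        If no start converges.
    DomainError
        If fewer than 8 samples are supplied.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size < 8 or t.size != y.size:
        raise DomainError("need at least 8 (t, y) samples")
    span = float(y.max() - y.min())
    if span < 1e-12:
        return SigmoidFit(float(y.mean()), 0.0, float(t.mean()), 1.0, 0.0)

    q = max(2, t.size // 4)
    b0 = float(np.mean(y[:q]))
    a0 = float(np.mean(y[-q:]) - b0)
    if a0 == 0.0:
        a0 = span if y[-1] >= y[0] else -span
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(y, kernel, mode="same")
    slope = np.gradient(smooth, t)
    t0_0 = float(t[np.argmax(np.abs(slope))])
    frac = (y - b0) / a0
    lo = np.nonzero(frac >= 0.1)[0]
    hi = np.nonzero(frac >= 0.9)[0]
    rise = (t[hi[0]] - t[lo[0]]) if (lo.size and hi.size and hi[0] > lo[0]) else (
        0.1 * (t[-1] - t[0])
    )
    k0 = math.log(81.0) / max(rise, 1e-3)

    def model(p, tt):
        b, a, t0, k = p
        return b + a / (1.0 + np.exp(-np.clip(k * (tt - t0), -500, 500)))

    def residuals(p):
        return model(p, t) - y

    rng = np.random.default_rng(seed)
    starts = [np.array([b0, a0, t0_0, k0])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.array(
                [
                    b0 + 0.1 * a0 * rng.standard_normal(),
                    a0 * rng.uniform(0.5, 1.5),
                    t0_0 + rng.uniform(-0.3, 0.3) * max(rise, 0.1),
                    k0 * rng.uniform(0.4, 2.5),
                ]
            )
        )
    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                residuals,
                p0,
                bounds=([-np.inf, -np.inf, t[0] - 10, 1e-3], [np.inf, np.inf, t[-1] + 10, 1e3]),
                max_nfev=2000,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("sigmoid fit failed from every start")
    b, a, t0, k = best.x
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return SigmoidFit(float(b), float(a), float(t0), float(k), rms)
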