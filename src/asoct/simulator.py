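"""Forward model: spectral interferograms of an eye phantom.

Image formation follows the standard spectral-domain OCT model under the
first-order Born approximation: each interface contributes a cosine fringe
2 a cos(2 k z) to the detected spectrum, where z is the optical path from
the active reference arm's zero-delay plane and a is the amplitude
reflectivity attenuated by the transmission of shallower interfaces.  The
finite spectral width of one camera pixel is modeled by boxcar sub-pixel
integration, which produces the sinc-shaped sensitivity roll-off with depth
without an explicit envelope term.

Rays enter the eye vertically (telecentric scan) and refract at each
interface by Snell's law in the scanned meridian, so the optical path to a
deep surface is accumulated along the bent ray.  This is the image-formation
model that the layer-by-layer refraction correction in :mod:`asoct.biometry`
inverts exactly.

Two reference arms are simulated: arm 1 with its zero-delay plane just above
the corneal apex, arm 2 with it just below the posterior lens, offset by the
inter-arm optical path difference (~11-13 mm depending on the eye).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, GeometryError
from .optics import SourceSpectrum, SpectrometerConfig, max_scan_depth
from .phantom import (
    CORNEA_ANTERIOR,
    IRIS_PLANE,
    ORDERED_SURFACES,
    EyePhantom,
    Interface,
    MediaStack,
)

#: Traversal order of phantom interfaces along a ray (iris between the
#: posterior cornea and the anterior lens).
TRAVERSAL_ORDER = (
    "cornea-anterior",
    "cornea-posterior",
    "iris-plane",
    "lens-anterior",
    "lens-posterior",
)


@dataclass(frozen=True)
class ArmGeometry:
    """Zero-delay placement of the two reference arms.

    ``arm1_z0`` is the optical depth of arm 1's zero-delay plane measured
    from the corneal anterior apex (negative = above the cornea).  Arm 2's
    plane sits ``opd_offset`` deeper.
    """

    opd_offset: float  # mm between the two reference arms
    arm1_z0: float = -0.5  # mm, zero-delay of arm 1 relative to the corneal apex

    def __post_init__(self):
        if self.opd_offset <= 0:
            raise DomainError("opd_offset must be positive")

    def zero_delay(self, arm: int) -> float:
        if arm == 1:
            return self.arm1_z0
        if arm == 2:
            return self.arm1_z0 + self.opd_offset
        raise DomainError(f"arm must be 1 or 2, got {arm}")


def recommended_arm_geometry(
    phantom: EyePhantom, standoff: float = 0.5, margin: float = 0.25
) -> ArmGeometry:
    """Arm geometry placing the zero-delay planes at the top and bottom of
    the anterior segment of ``phantom``.

    Arm 1 sits ``standoff`` mm above the corneal apex; arm 2 sits ``margin``
    mm below the posterior lens apex (in optical path).  For the default
    phakic eye the inter-arm offset comes to ~12.8 mm.
    """
    return ArmGeometry(
        opd_offset=standoff + phantom.total_optical_depth + margin, arm1_z0=-standoff
    )


@dataclass(frozen=True)
class Reflector:
    """One reflecting point seen by an A-line."""

    opd: float  # signed optical path from the zero-delay plane, mm
    amplitude: float  # amplitude reflectivity including overlying transmission
    label: str = ""
    lateral: float = 0.0  # lateral position of the actual hit point, mm


@dataclass(frozen=True)
class NoiseParams:
    """Additive read noise and Poisson shot noise of the line camera.

    Intensities are in units of the unit-peak source spectrum; shot noise is
    modeled by drawing photon counts at ``shot_photons`` photons per unit
    intensity (scaled by the exposure time relative to 77 us).
    """

    read_noise_std: float = 0.005
    shot_photons: float = 1.0e4

    def __post_init__(self):
        if self.read_noise_std < 0 or self.shot_photons < 0:
            raise DomainError("noise parameters must be >= 0")


@dataclass
class Interferogram:
    """Raw spectrum of one A-line."""

    intensities: np.ndarray  # (n_pixels,), non-negative
    wavelength_axis: np.ndarray  # nm per pixel
    exposure_time: float = 77.0  # us
    arm_id: int = 1

    def __post_init__(self):
        if np.any(self.intensities < 0):
            raise DomainError("interferogram intensities must be non-negative")


@dataclass
class RawFrame:
    """Stack of raw interferograms forming one B-scan acquisition."""

    interferograms: np.ndarray  # (n_alines, n_pixels)
    wavelength_axis: np.ndarray
    lateral_axis: np.ndarray  # mm, A-line centers
    arm_id: int
    exposure_time: float = 77.0
    seed: int | None = None

    @property
    def n_alines(self) -> int:
        return self.interferograms.shape[0]


# ---------------------------------------------------------------------------
# Ray tracing
# ---------------------------------------------------------------------------


def _intersect(p_lat, p_z, u_lat, u_z, iface: Interface):
    """Intersection of the ray p + t u with a surface; None if missed.

    Returns (t, q_lat, q_z, n_lat, n_z) with the unit normal oriented
    against the ray (q . n < 0 side).
    """
    eps = 1e-9
    if iface.is_flat:
        if abs(u_z) < eps:
            return None
        t = (iface.apex_z - p_z) / u_z
        if t <= eps:
            return None
        q_lat, q_z = p_lat + t * u_lat, iface.apex_z
        n_lat, n_z = 0.0, -math.copysign(1.0, u_z)
    else:
        c_lat, c_z = 0.0, iface.apex_z + iface.radius
        r = abs(iface.radius)
        d_lat, d_z = p_lat - c_lat, p_z - c_z
        b = d_lat * u_lat + d_z * u_z
        c0 = d_lat * d_lat + d_z * d_z - r * r
        disc = b * b - c0
        if disc <= 0:
            return None
        sq = math.sqrt(disc)
        branch_sign = -math.copysign(1.0, iface.radius)
        t_hit = None
        for t in sorted((-b - sq, -b + sq)):
            if t <= eps:
                continue
            q_z = p_z + t * u_z
            if math.copysign(1.0, q_z - c_z) == branch_sign:
                t_hit = t
                break
        if t_hit is None:
            return None
        t = t_hit
        q_lat, q_z = p_lat + t * u_lat, p_z + t * u_z
        n_lat, n_z = (q_lat - c_lat) / r, (q_z - c_z) / r
        if n_lat * u_lat + n_z * u_z > 0:
            n_lat, n_z = -n_lat, -n_z
    aq = abs(q_lat)
    if not (iface.inner_aperture <= aq <= iface.aperture):
        return None
    return t, q_lat, q_z, n_lat, n_z


def _refract(u_lat, u_z, n_lat, n_z, n1, n2):
    """Snell refraction of unit direction u at normal n (2-D meridian)."""
    if n1 == n2:
        return u_lat, u_z
    r = n1 / n2
    cos1 = -(u_lat * n_lat + u_z * n_z)
    sin2sq = r * r * (1.0 - cos1 * cos1)
    if sin2sq > 1.0:
        raise DomainError("total internal reflection encountered")
    cos2 = math.sqrt(1.0 - sin2sq)
    f = r * cos1 - cos2
    return r * u_lat + f * n_lat, r * u_z + f * n_z


def trace_reflectors(
    phantom: EyePhantom,
    x: float,
    arm_geometry: ArmGeometry | None = None,
    arm: int = 1,
) -> list[Reflector]:
    """Reflectors seen by the A-line entering vertically at lateral ``x``.

    The ray starts in air above the cornea, refracts at each curved
    interface it hits, and accumulates optical path n * length along its
    bent trajectory.  A surface whose aperture the ray misses contributes
    nothing (and does not refract).  The returned ``opd`` values are signed
    relative to the requested arm's zero-delay plane.
    """
    if abs(x) > phantom.lateral_extent / 2:
        raise DomainError(f"|x|={abs(x)} exceeds lateral extent/2")
    z0 = arm_geometry.zero_delay(arm) if arm_geometry else 0.0
    media = phantom.media
    order = [lbl for lbl in TRAVERSAL_ORDER if any(i.label == lbl for i in phantom.interfaces)]

    p_lat, p_z = float(x), -10.0  # start well above the eye, in air
    u_lat, u_z = 0.0, 1.0
    # optical path measured from the corneal-apex plane z=0; the air segment
    # above it contributes its (negative) geometric start position
    opl = p_z * media.n_air
    n_current = media.n_air
    trans = 1.0
    out = []
    for lbl in order:
        iface = phantom.surface(lbl)
        hit = _intersect(p_lat, p_z, u_lat, u_z, iface)
        if hit is None:
            continue
        t, q_lat, q_z, n_lat, n_z = hit
        opl += n_current * t
        out.append(
            Reflector(
                opd=opl - z0,
                amplitude=math.sqrt(iface.reflectivity) * trans,
                label=lbl,
                lateral=q_lat,
            )
        )
        trans *= 1.0 - iface.reflectivity
        p_lat, p_z = q_lat, q_z
        n_after = media.index_after(lbl)
        u_lat, u_z = _refract(u_lat, u_z, n_lat, n_z, n_current, n_after)
        n_current = n_after
    return out


def optical_path_traces(
    phantom: EyePhantom,
    xs: np.ndarray,
    arm_geometry: ArmGeometry | None = None,
    arm: int = 1,
    surfaces=ORDERED_SURFACES,
) -> dict[str, np.ndarray]:
    """Per-surface optical-path depth vs A-line position (NaN where absent)."""
    xs = np.asarray(xs, dtype=float)
    out = {lbl: np.full(xs.shape, np.nan) for lbl in surfaces}
    for i, x in enumerate(xs):
        for refl in trace_reflectors(phantom, float(x), arm_geometry, arm):
            if refl.label in out:
                out[refl.label][i] = refl.opd
    return out


# ---------------------------------------------------------------------------
# Interferogram synthesis
# ---------------------------------------------------------------------------


def _sub_pixel_wavelengths(config: SpectrometerConfig, source: SourceSpectrum, n_sub: int):
    lam = config.wavelength_axis(source)
    dl = config.delta_lambda
    if n_sub <= 1:
        return lam, lam[:, None]
    offs = ((np.arange(n_sub) + 0.5) / n_sub - 0.5) * dl
    return lam, lam[:, None] + offs[None, :]


def synthesize_interferogram(
    reflectors,
    config: SpectrometerConfig,
    source: SourceSpectrum,
    noise: NoiseParams | None = None,
    seed: int | np.random.Generator | None = None,
    n_sub: int = 8,
    exposure_time: float = 77.0,
    arm_id: int = 1,
) -> Interferogram:
    """Raw camera spectrum for a set of reflectors.

    I(p) = S(lambda_p) + sum_i 2 a_i < S(lambda) cos(2 k(lambda) z_i) >_pixel

    where the fringe term is averaged over ``n_sub`` boxcar sub-samples of
    the pixel's spectral width (finite spectral resolution -> sinc-shaped
    roll-off).  ``reflectors`` is an iterable of :class:`Reflector` or
    ``(opd_mm, amplitude)`` pairs; an empty set yields the bare source
    spectrum.  Gaussian read noise and Poisson shot noise are added when
    ``noise`` is given; negative values are clipped at zero.
    """
    lam, lam_sub = _sub_pixel_wavelengths(config, source, n_sub)
    intensity = source.spectral_density(lam).copy()
    zmax = max_scan_depth(source.center_wavelength, config.delta_lambda)
    if reflectors:
        s_sub = source.spectral_density(lam_sub)
        k_sub = 2.0 * math.pi / lam_sub  # nm^-1
        for refl in reflectors:
            z, a = (refl.opd, refl.amplitude) if isinstance(refl, Reflector) else refl
            if a < 0:
                raise DomainError("reflector amplitude must be >= 0")
            if abs(z) > 2.0 * zmax:
                warnings.warn(
                    f"reflector at {z:.2f} mm beyond twice the scan depth; aliasing",
                    stacklevel=2,
                )
            fringe = s_sub * np.cos(2.0 * k_sub * (z * 1.0e6))
            intensity += 2.0 * a * fringe.mean(axis=1)
    if noise is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        intensity = _apply_noise(intensity, noise, rng, exposure_time)
    intensity = np.clip(intensity, 0.0, None)
    return Interferogram(intensity, lam, exposure_time, arm_id)


def _apply_noise(intensity, noise: NoiseParams, rng, exposure_time):
    out = intensity
    if noise.shot_photons > 0:
        scale = noise.shot_photons * exposure_time / 77.0
        out = rng.poisson(np.clip(out, 0.0, None) * scale) / scale
    if noise.read_noise_std > 0:
        out = out + rng.normal(0.0, noise.read_noise_std, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# B-scan pair
# ---------------------------------------------------------------------------


def simulate_bscan_pair(
    phantom: EyePhantom,
    config: SpectrometerConfig,
    source: SourceSpectrum,
    arm_geometry: ArmGeometry | None = None,
    n_alines: int = 1024,
    noise: NoiseParams | None = NoiseParams(),
    seed: int = 0,
    n_sub: int = 8,
    specular_artifact: bool = True,
    specular_alines: int | None = None,
    specular_amplitude: float = 5.0,
    full_well: float = 4.0,
    exposure_time: float = 77.0,
    inter_arm_motion: tuple[float, float] = (0.0, 0.0),
) -> tuple[RawFrame, RawFrame]:
    """Simulate the sequentially acquired frame pair (arm 1, then arm 2).

    Both frames scan the same ``n_alines`` lateral positions across the
    phantom's lateral extent.  The corneal-apex specular reflex is modeled
    as a strong extra reflector on the central ``specular_alines`` A-lines
    (default: the 50 A-lines of a 2048-line scan, i.e. ~0.34 mm, scaled to
    the actual sampling) whose fringes saturate the camera at ``full_well``
    (amplitude saturation), producing the vertical hyper-reflective stripe
    that the profile analysis later excludes.  ``inter_arm_motion`` = (dz_mm, dx_mm)
    applies a small rigid axial/lateral offset to the arm-2 acquisition to
    emulate eye movement between the two acquisitions.

    The same (phantom, seed) pair yields bit-identical output.
    """
    if n_alines < 2:
        raise DomainError("n_alines must be >= 2")
    arm_geometry = arm_geometry or recommended_arm_geometry(phantom)
    rng = np.random.default_rng(seed)
    xs = (np.arange(n_alines) + 0.5) / n_alines * phantom.lateral_extent
    xs = xs - phantom.lateral_extent / 2.0
    lam, lam_sub = _sub_pixel_wavelengths(config, source, n_sub)
    s_pix = source.spectral_density(lam)
    s_sub = source.spectral_density(lam_sub)
    k_sub = 2.0 * math.pi / lam_sub

    if specular_alines is None:
        specular_alines = max(2, round(50 * n_alines / 2048))
    c0 = n_alines // 2
    spec_cols = set(range(c0 - specular_alines // 2, c0 - specular_alines // 2 + specular_alines))

    frames = []
    for arm in (1, 2):
        dz, dx = inter_arm_motion if arm == 2 else (0.0, 0.0)
        data = np.empty((n_alines, config.n_pixels), dtype=float)
        for i, x in enumerate(xs):
            x_eff = float(np.clip(x + dx, -phantom.lateral_extent / 2, phantom.lateral_extent / 2))
            refl = trace_reflectors(phantom, x_eff, arm_geometry, arm)
            pairs = [(r.opd + dz, r.amplitude) for r in refl]
            if specular_artifact and i in spec_cols:
                apex = next((r.opd for r in refl if r.label == CORNEA_ANTERIOR), None)
                if apex is not None:
                    pairs.append((apex + dz, specular_amplitude))
            row = s_pix.copy()
            for z, a in pairs:
                row = row + 2.0 * a * (s_sub * np.cos(2.0 * k_sub * (z * 1.0e6))).mean(axis=1)
            data[i] = row
        if noise is not None:
            data = _apply_noise(data, noise, rng, exposure_time)
        np.clip(data, 0.0, full_well, out=data)
        frames.append(
            RawFrame(
                interferograms=data,
                wavelength_axis=lam,
                lateral_axis=xs,
                arm_id=arm,
                exposure_time=exposure_time,
                seed=seed,
            )
        )
    return frames[0], frames[1]
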