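"""Light source and spectrometer performance model.

Three spectrometer designs share the same optical train (1800 lines/mm
transmission grating at Littrow incidence for the 840 nm center wavelength,
a 240 mm focusing lens, 10 um camera pixels) and differ in the line camera:

========  ======  ===========  ===================
system    camera  pixels/line  max line rate (A/s)
========  ======  ===========  ===================
system1   CCD     2048         24,000
system2   CCD     4096         12,000
system3   CMOS    4096         70,000
========  ======  ===========  ===================

The per-pixel spectral resolution delta_lambda follows from the grating's
angular dispersion imaged onto one pixel; it sets the maximum depth
z_max = lambda0^2 / (4 delta_lambda) that the Fourier reconstruction can
represent.  The source bandwidth sets the theoretical axial resolution
dz = (2 ln 2 / pi) lambda0^2 / Delta_lambda.  A 2048-pixel camera truncates
the source spectrum to roughly half its extent, trading axial resolution
for the same scan depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .errors import DomainError, OpticsError


@dataclass(frozen=True)
class SourceSpectrum:
    """Gaussian superluminescent-diode spectrum, unit peak spectral density."""

    center_wavelength: float = 840.0  # nm
    fwhm_bandwidth: float = 50.0  # nm
    power: float = 1.25  # mW, metadata only

    def __post_init__(self):
        if self.center_wavelength <= 0 or self.fwhm_bandwidth <= 0:
            raise DomainError("center wavelength and bandwidth must be positive")

    @property
    def sigma(self) -> float:
        """Gaussian standard deviation in nm."""
        return self.fwhm_bandwidth / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def spectral_density(self, wavelength_nm):
        """Unit-peak spectral density at the given wavelength(s) (nm)."""
        lam = np.asarray(wavelength_nm, dtype=float)
        u = (lam - self.center_wavelength) / self.fwhm_bandwidth
        return np.exp(-4.0 * math.log(2.0) * u * u)


@dataclass(frozen=True)
class SpectrometerConfig:
    """Optical and camera parameters of one spectrometer."""

    name: str
    camera: str
    n_pixels: int
    max_line_rate: float
    pixel_pitch: float = 10.0  # um
    grating_density: float = 1800.0  # lines/mm
    focal_length: float = 240.0  # mm
    design_wavelength: float = 840.0  # nm

    def __post_init__(self):
        if min(self.n_pixels, self.pixel_pitch, self.grating_density, self.focal_length) <= 0:
            raise DomainError("spectrometer parameters must be positive")

    @property
    def delta_lambda(self) -> float:
        """Per-pixel spectral resolution (nm) at the design wavelength."""
        return per_pixel_spectral_resolution(self)

    @property
    def span(self) -> float:
        """Spectral span on the detector, nm."""
        return self.n_pixels * self.delta_lambda

    def wavelength_axis(self, source: SourceSpectrum | None = None) -> np.ndarray:
        """Per-pixel wavelengths (nm), centered on the source wavelength."""
        lam0 = source.center_wavelength if source else self.design_wavelength
        dl = self.delta_lambda
        p = np.arange(self.n_pixels)
        return lam0 + (p - (self.n_pixels - 1) / 2.0) * dl


_PRESETS = {
    "system1": dict(camera="CCD", n_pixels=2048, max_line_rate=24_000.0),
    "system2": dict(camera="CCD", n_pixels=4096, max_line_rate=12_000.0),
    "system3": dict(camera="CMOS", n_pixels=4096, max_line_rate=70_000.0),
}


def system_preset(name: str) -> SpectrometerConfig:
    """Named preset for one of the three spectrometer designs."""
    try:
        return SpectrometerConfig(name=name, **_PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown system {name!r}; choose from {sorted(_PRESETS)}") from None


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def per_pixel_spectral_resolution(
    config: SpectrometerConfig, source: SourceSpectrum | None = None
) -> float:
    """Wavelength increment per camera pixel, in nm.

    Assumes Littrow incidence at the center wavelength, so the diffraction
    angle satisfies sin(theta) = lambda0 / (2 d) with d the grating period.
    The reciprocal linear dispersion at the focal plane is d cos(theta) / f,
    and one pixel of pitch p therefore subtends

        delta_lambda = (d cos(theta) / f) * p.

    Raises
    ------
    OpticsError
        If lambda0 >= 2 d (no real first-order diffraction angle).
    """
    lam0 = source.center_wavelength if source else config.design_wavelength
    d_nm = 1.0e6 / config.grating_density  # grating period in nm
    s = lam0 / (2.0 * d_nm)
    if s >= 1.0:
        raise OpticsError(
            f"no real diffraction angle: lambda0 = {lam0} nm >= 2d = {2 * d_nm:.1f} nm"
        )
    cos_theta = math.sqrt(1.0 - s * s)
    pitch_nm = config.pixel_pitch * 1.0e3
    f_nm = config.focal_length * 1.0e6
    return d_nm * cos_theta * pitch_nm / f_nm


def max_scan_depth(lambda0_nm: float, delta_lambda_nm: float) -> float:
    """Maximum detectable depth in air, mm: z_max = lambda0^2 / (4 delta_lambda)."""
    if lambda0_nm <= 0 or delta_lambda_nm <= 0:
        raise DomainError("wavelength and spectral resolution must be positive")
    return lambda0_nm * lambda0_nm / (4.0 * delta_lambda_nm) * 1.0e-6


def theoretical_axial_resolution(lambda0_nm: float, fwhm_bandwidth_nm: float) -> float:
    """FWHM axial resolution in air (um) of a Gaussian source.

    dz = (2 ln 2 / pi) * lambda0^2 / Delta_lambda, the coherence-length
    formula; this is the amplitude FWHM of the reconstructed point spread
    function when the full spectrum reaches the detector.
    """
    if lambda0_nm <= 0 or fwhm_bandwidth_nm <= 0:
        raise DomainError("wavelength and bandwidth must be positive")
    return (2.0 * math.log(2.0) / math.pi) * lambda0_nm**2 / fwhm_bandwidth_nm * 1.0e-3


def sensitivity_from_psf(signal_peak: float, noise: float, od: float = 2.0) -> float:
    """Sensitivity in dB: 10 log10(S / sigma) + 20 * OD.

    ``signal_peak`` and ``noise`` are linear power quantities (peak power of
    the point spread function and the noise-floor power).  The additive
    20 * OD term compensates the double-pass attenuation of a neutral
    density filter of optical density OD in the sample arm.
    """
    if signal_peak <= 0 or noise <= 0:
        raise DomainError("signal peak and noise must be positive")
    if od < 0:
        raise DomainError("optical density must be >= 0")
    return 10.0 * math.log10(signal_peak / noise) + 20.0 * od


def effective_source_window(
    config: SpectrometerConfig, source: SourceSpectrum
) -> tuple[float, float, float]:
    """Spectral window seen by the camera and the captured energy fraction.

    Returns ``(lambda_min, lambda_max, fraction)`` where the window is
    centered on the source wavelength with width n_pixels * delta_lambda and
    the fraction is the integral of the area-normalized Gaussian spectral
    density over the window.
    """
    half = 0.5 * config.n_pixels * per_pixel_spectral_resolution(config, source)
    lam0 = source.center_wavelength
    fraction = float(erf(half / (source.sigma * math.sqrt(2.0))))
    return lam0 - half, lam0 + half, fraction


@dataclass(frozen=True)
class PerformanceFigures:
    """Analytic performance summary of a spectrometer + source pairing."""

    name: str
    delta_lambda: float  # nm per pixel
    max_depth_air: float  # mm
    theoretical_axial_resolution: float  # um
    depth_per_pixel: float  # mm per depth bin
    captured_energy_fraction: float

    def as_dict(self) -> dict:
        return {
            "system": self.name,
            "delta_lambda_nm": self.delta_lambda,
            "max_depth_air_mm": self.max_depth_air,
            "theoretical_axial_resolution_um": self.theoretical_axial_resolution,
            "depth_per_pixel_mm": self.depth_per_pixel,
            "captured_energy_fraction": self.captured_energy_fraction,
        }


def performance_figures(
    config: SpectrometerConfig, source: SourceSpectrum | None = None
) -> PerformanceFigures:
    """Compute the analytic performance figures for one system."""
    source = source or SourceSpectrum()
    dl = per_pixel_spectral_resolution(config, source)
    zmax = max_scan_depth(source.center_wavelength, dl)
    _, _, frac = effective_source_window(config, source)
    return PerformanceFigures(
        name=config.name,
        delta_lambda=dl,
        max_depth_air=zmax,
        theoretical_axial_resolution=theoretical_axial_resolution(
            source.center_wavelength, source.fwhm_bandwidth
        ),
        depth_per_pixel=zmax / (config.n_pixels / 2),
        captured_energy_fraction=frac,
    )
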