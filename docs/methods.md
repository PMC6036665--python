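# Methods

`asoct` simulates and processes long-scan-depth spectral-domain OCT (SD-OCT)
of the ocular anterior segment with two switchable reference arms, and
extracts accommodation biometry from the fused images. This note records the
models, the numerical choices, and what the synthetic data does and does not
emulate.

## Eye phantom

The phantom is a 2-D meridional section: four refractive interfaces
(anterior/posterior cornea, anterior/posterior lens) modeled as circular
arcs plus an annular iris plane at the anterior-lens apex depth. Defaults
describe a relaxed adult phakic eye: CCT 0.55 mm, ACD 3.38 mm, CLT 4.76 mm,
radii RAC 7.47, RPC 6.46, RAL 10.20, RPL 6.12 mm; refractive indices at
840 nm are 1.387 (cornea), 1.342 (aqueous), 1.408 (lens). Radii are signed
(positive = center of curvature posterior to the apex; the posterior lens is
stored negative and reported as a magnitude). The lens surfaces carry the
pupil radius (default 2 mm) as their aperture, which is how iris occlusion
enters the image. Surfaces are arcs, not conicoids: the instrument images
single meridians, so asphericity adds nothing testable here.

The pseudophakic (IOL) phantom is synthetic in every respect the literature
does not pin down: ACD 4.2 mm, implant thickness 0.8 mm, biconvex 16 mm
radii, same media.

Accommodation is a logistic time course per quantity,
`q(t) = baseline + amplitude / (1 + exp(-k (t - t0)))`, applied to ACD and
CLT; CCT is constant by construction and an IOL's thickness is pinned at
zero amplitude. Defaults: ACD amplitude -0.09 mm and CLT +0.04 mm (the
relaxed-to-accommodated differences of the default geometry), onset
t0 = 1.5 s (a 4 D stimulus at 1 s plus ~0.5 s latency), rate k = 8 /s so the
10-90% rise takes ~0.55 s. Frame sampling is floor(duration x rate) + 1
frames starting at t = 0; 3.72 s at 8.3 frames/s gives 31 frames.

## Spectrometer and source model

All three systems share one optical train — 1800 lines/mm transmission
grating at Littrow incidence for 840 nm, 240 mm focusing lens, 10 um pixel
pitch — and differ in the camera: 2048-px CCD (24 kHz), 4096-px CCD
(12 kHz), 4096-px CMOS (70 kHz). The per-pixel spectral resolution follows
from the grating equation, `delta_lambda = (d cos theta / f) p` with
`sin theta = lambda0 / 2d`, giving 0.0152 nm; the literal printed value
0.015 nm corresponds to a scan depth `lambda0^2 / 4 delta_lambda` of
11.76 mm in air. `delta_lambda` is treated as constant across the detector
(linear-in-wavelength sampling); dispersion curvature is ignored because a
single resolution figure is all the design states.

The source is a unit-peak Gaussian, 840 nm center, 50 nm FWHM. Its
coherence-length resolution `(2 ln 2 / pi) lambda0^2 / Delta_lambda` is
6.23 um in air — the FWHM of the reconstructed *amplitude* PSF when the
whole spectrum reaches the detector. The 4096-px window spans 62 nm and
captures only 0.856 of the Gaussian's area (truncating it at 34% of peak),
which broadens the simulated PSF to ~8.2 um; the 2048-px window (0.535
captured) roughly doubles it (~14.5 um). This ordering — theory < 4096-px
systems < 2048-px system — is the structural fact the package tests; the
bench-measured 7.0/10.4 um sit in the same order and depend on hardware
details (true pixel response, optical aberrations) outside the model.

## Forward model

First-order Born: each interface contributes a fringe `2 a cos(2 k z)` to
the spectrum, with `a = sqrt(R)` attenuated by `prod(1 - R_shallower)`, and
no multiple scattering or speckle — a deterministic layered phantom is what
boundary detection needs. Rays enter vertically (telecentric scan) and
refract at each interface by Snell's law in the meridian plane; `z` is the
optical path accumulated along the bent ray minus the active arm's
zero-delay offset. Modeling refraction in the forward direction is what
makes the layer-by-layer correction (below) its exact inverse, which the
round-trip acceptance check exploits.

Finite spectral resolution is not an analytic envelope: each pixel averages
the fringe over `n_sub = 8` boxcar sub-samples of its spectral width, and
the sinc-shaped sensitivity roll-off *emerges*; the analytic
`sinc^2(z / 2 z_max)` is kept as the independent oracle (agreement within
~0.05 dB to 0.8 z_max). Noise is Gaussian read noise (default sigma = 0.005
of the source peak) plus Poisson shot noise (10^4 photons per unit
intensity, scaled by exposure). The corneal-apex specular reflex is an
extra strong reflector on the central A-lines (50 of a 2048-line scan,
~0.34 mm, scaled with the sampling) whose fringes clip at the camera full
well — the vertical saturated stripe the profile analysis must exclude.

Arm geometry: arm 1's zero-delay plane sits 0.5 mm above the corneal apex,
arm 2's below the posterior lens. For the default eye the anterior segment
is 12.0 mm of optical path, so the recommended inter-arm offset is
~12.75 mm; "about 11 mm" is the right order for shorter eyes, but an offset
smaller than the total optical length would fold the posterior lens across
arm 2's zero-delay plane (conjugate ambiguity), so the default is computed
per phantom — matching the practice of adjusting the offset per eye.

## Reconstruction

Per A-line: (1) subtract the reference background as the least-squares
scaled source spectrum; (2) resample uniform-wavelength to uniform-
wavenumber; (3) Hann window (off for DFT-oracle tests); (4) FFT, keep the
positive half, 20 log10 magnitude. The resampling interpolates on a 32x
band-limited (FFT) upsampled grid after a 4% Tukey edge taper: direct cubic
interpolation of near-Nyquist fringes costs >1 dB of peak amplitude at
depth and low-order interpolation residue raises a depth-dependent leakage
pedestal; both sit below the read-noise floor with this scheme. Depth
calibration comes from the actual wavenumber grid
(`z_bin = pi / (N_fft delta_k)`).

PSF metrics: the peak is refined by a 3-point parabola on the log
magnitude; FWHM is measured at half maximum of the linear *amplitude*
(peak - 6 dB on the 20 log10 plot), the convention under which the Gaussian
coherence-length formula is the exact reference; the noise floor is the
median of bins >0.5 mm from the peak (median, not mean, to resist peak
leakage). Sensitivity is `10 log10(S / sigma) + 20 OD` with S and sigma as
powers; the `20 OD` term books the double-pass attenuation of the bench's
OD 2.0 neutral-density filter and is purely additive here. The roll-off
experiment measures the floor once from a signal-free acquisition and
reuses it across depths, as on a bench; its default noise is a faint read
noise (1e-4) because a strictly noise-free run would report the processing
chain's numerical leakage floor, which varies with depth.

## Dual-arm fusion

The arm-2 frame is axially flipped into anatomical orientation, then
registered to arm 1 by normalized cross-correlation of the structure-richest
band (iris plane + anterior lens — the features both arms share), searched
over +-30 px of translation around the nominal offset and +-3 deg of
rotation: a coarse 1 deg grid (decimated for speed) locates the angle, then
the residual rotation is estimated from the differential axial shift of the
band's left and right halves and a full-resolution pass fixes the
translation (parabolic sub-pixel peaks). The differential estimator is used
instead of maximizing correlation over the angle because interpolation blur
slightly inflates the NCC at nonzero angles and biases that maximization
away from zero. A best correlation below 0.2 raises a registration failure.
On known-transform pairs the estimate is good to ~0.03 deg / 0.3 px.

Fusion resamples arm 2 by the estimated transform onto arm 1's grid
extended to the full depth and blends linearly with per-depth weights
proportional to each arm's modeled sinc^2 power sensitivity (weights sum to
one where both contribute; single-arm regions take weight one) — overlap,
not cropping, so no sensitivity valley and no seam. The reported
sensitivity profile is the per-depth best-arm model, and the combined
drop-off is its max-minus-min down to arm 2's zero-delay plane; with the
arm offset matched to the imaged depth the profile is V-shaped with the
minimum at mid-depth (a linear 60 dB/11 mm roll-off folds to exactly 30 dB).

## Biometry

Reflectivity profiles average (linear power) 50 A-scans on each side of the
excluded central band (50 A-scans of a 1024-line frame; both widths scale
with the actual sampling). Principal peaks with >=6 dB prominence, clustered
at >=0.3 mm separation, are labeled in anatomical order; corneal sub-peaks
(Bowman's layer, ~15 um deep) are reported when the axial resolution
separates them — they resolve at 7 um FWHM and merge at 11 um.

Boundary tracing marches outward from the band edges, accepting the local
maximum within 3 depth pixels of its neighbor when it clears the column's
median floor by 6 dB; sub-pixel parabola per column, median filter with
outlier rejection, interior gaps interpolated, manual override points
honored exactly. Twelve consecutive rejections end a surface (the lens
surfaces end at the pupil margin this way). Gap-interpolated columns are
excluded from the curvature fits: a chord interpolated across the central
band sits several micrometres shallow of the arc and would bias the radius.

Refraction correction is layer-by-layer ray tracing: rays enter vertically;
at each corrected interface the local normal comes from a circle fitted to
that interface's already-corrected trace; Snell's law bends the ray and the
next sample lies a geometric distance (optical increment)/n along it. With
all indices 1 it is the identity; on analytic traces it recovers the
generating radii to <1e-6 relative and the acceptance round trip (correct,
re-run the forward model, compare optical paths) closes below 1 um RMS.

Circle fits are algebraic (Kasa) + geometric least squares, with 3-sigma
(MAD-based) outlier rejection in the biometry path; collinear points return
a flat sentinel. Fit apertures: cornea +-3 mm, lens surfaces the pupil
aperture (the iris hides the periphery). CCT/ACD/CLT are apex differences,
the apex interpolated across the excluded band by a quadratic fitted to
both flanks (|x| <= 1.5 mm). ACD is posterior cornea to anterior lens.
Radii are magnitudes.

Sigmoid fits use nonlinear least squares with data-driven initialization
(baseline/amplitude from the first/last quartiles, t0 at the steepest
smoothed slope, k from the 10-90% rise time) and five jittered restarts.
A constant series short-circuits to amplitude zero. At the dynamic protocol
(31 frames, 8.3 frames/s, 5 um noise) amplitude and rate recover within a
few percent for the phakic eye; for a 20 um IOL shift the rate k is barely
identified (the rise spans ~2 samples) while amplitude and onset remain
reliable — a real limitation of the protocol, not of the fit.

## Problem sizes

Unit and property tests run on a 512-px detector variant and 384-A-line
frames; the end-to-end recovery runs the 4096-px CMOS system at 1024
A-lines (the dynamic-protocol lateral sampling) with fixed seeds, and the
full-resolution dynamic demonstration uses 256-A-line frames. These sizes
keep a complete run in minutes on one core while leaving every tolerance
(10/20 um, 2% radii) dominated by the method, not the grid.

## Limitations

No speckle, no multiple scattering, no dispersion mismatch between arms
(assumed compensated), no galvanometer distortion, no chromatic index
variation, no Kappa-angle or fixation modeling, no 3-D scan patterns, and
no attempt to predict absolute hardware sensitivities (101/111/103 dB) or
measured drop-offs — those depend on camera electronics and optics outside
the model; the package reproduces their orderings and structural behavior
instead. Passing tests therefore show the processing chain is correct and
unbiased on idealized layered eyes, not that a clinical instrument will
reach these tolerances on real tissue.
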