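"""Reflectivity profiles, boundary tracing, refraction correction, circle
fits and sigmoid dynamics."""

import numpy as np
import pytest

from asoct import (
    DomainError,
    IncompleteSegmentationError,
    MediaStack,
    axial_profile,
    build_phantom,
    detect_boundary_peaks,
    default_phantom,
    fit_circle,
    fit_sigmoid,
    optical_path_traces,
    refraction_correct,
    compute_biometry,
)
from asoct.biometry import (
    BoundaryTrace,
    ReflectivityProfile,
    SOURCE_AUTO,
    _apex_depth,
    trace_boundaries,
)
from asoct.phantom import ORDERED_SURFACES, SigmoidParams


class _Image:
    def __init__(self, raster, dpp=0.005, lpp=0.0137):
        self.raster = raster
        self.depth_per_pixel = dpp
        self.lateral_per_pixel = lpp


class TestAxialProfile:
    def test_constant_image_gives_flat_profile(self):
        img = _Image(np.full((256, 300), -12.0))
        prof = axial_profile(img, strip_halfwidth_alines=50, exclude_halfwidth=25)
        np.testing.assert_allclose(prof.values, -12.0, atol=1e-9)

    def test_central_stripe_excluded_from_average(self):
        raster = np.full((256, 300), -30.0)
        raster[:, 150 - 25 : 150 + 25] = 40.0  # saturated specular stripe
        prof = axial_profile(_Image(raster), strip_halfwidth_alines=50,
                             exclude_halfwidth=25)
        np.testing.assert_allclose(prof.values, -30.0, atol=1e-9)

    def test_too_narrow_image_rejected(self):
        with pytest.raises(DomainError):
            axial_profile(_Image(np.zeros((64, 120))))


def synthetic_profile(peak_depths, widths_um, amps_db, depth_step_mm=0.002,
                      extent_mm=14.0, floor_db=-40.0):
    d = np.arange(0.0, extent_mm, depth_step_mm)
    v = np.full_like(d, floor_db)
    lin = 10 ** (v / 10.0)
    for z, w, a in zip(peak_depths, widths_um, amps_db):
        sigma = w / 1e3 / 2.3548200450309493
        lin += 10 ** (a / 10.0) * np.exp(-0.5 * ((d - z) / sigma) ** 2)
    return ReflectivityProfile(depths=d, values=10 * np.log10(lin))


class TestDetectBoundaryPeaks:
    def anatomy(self, extra=(), widths=()):
        depths = [0.5, 1.26, 5.8, 12.0] + list(extra)
        w = [10, 10, 10, 10] + list(widths)
        amps = [0, -6, -8, -10] + [-3] * len(extra)
        return depths, w, amps

    def test_four_principal_peaks_labeled_in_order(self):
        prof = synthetic_profile(*self.anatomy())
        peaks = detect_boundary_peaks(prof)
        assert list(peaks.principal) == list(ORDERED_SURFACES)
        assert peaks.principal["cornea-anterior"] == pytest.approx(0.5, abs=0.01)
        assert peaks.principal["lens-posterior"] == pytest.approx(12.0, abs=0.01)

    def test_bowman_subpeaks_resolved_at_7um(self):
        """Two corneal sub-surfaces ~15 um apart resolve at 7 um axial
        resolution (distinct reflectivity peaks)."""
        prof = synthetic_profile([0.5, 0.515, 1.26, 5.8, 12.0],
                                 [7, 7, 10, 10, 10], [0, -1, -6, -8, -10],
                                 depth_step_mm=0.001)
        peaks = detect_boundary_peaks(prof, min_prominence_db=3.0)
        assert len(peaks.sub_peaks) >= 2

    def test_bowman_subpeaks_merge_at_11um(self):
        prof = synthetic_profile([0.5, 0.515, 1.26, 5.8, 12.0],
                                 [11, 11, 10, 10, 10], [0, -1, -6, -8, -10],
                                 depth_step_mm=0.001)
        peaks = detect_boundary_peaks(prof, min_prominence_db=3.0)
        assert len(peaks.sub_peaks) < 2

    def test_monotone_ramp_has_no_peaks(self):
        prof = ReflectivityProfile(depths=np.arange(0, 14, 0.01),
                                   values=np.linspace(-40, -10, 1400))
        with pytest.raises(IncompleteSegmentationError):
            detect_boundary_peaks(prof)

    def test_missing_lens_reported_incomplete(self):
        prof = synthetic_profile([0.5, 1.26], [10, 10], [0, -6])
        with pytest.raises(IncompleteSegmentationError) as exc:
            detect_boundary_peaks(prof)
        assert len(exc.value.found) == 2


class TestFitCircle:
    def test_unit_circle_from_three_points(self):
        c = fit_circle([0.0, 1.0, 0.0], [1.0, 0.0, -1.0])
        assert abs(c.radius) == pytest.approx(1.0, abs=1e-9)
        assert c.center == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_exact_on_noiseless_arc(self):
        x = np.linspace(-3, 3, 100)
        z = 5.0 + 7.47 - np.sqrt(7.47**2 - x**2)
        c = fit_circle(x, z)
        assert c.radius == pytest.approx(7.47, rel=1e-9)

    def test_sign_negative_for_posterior_lens_shape(self):
        x = np.linspace(-2, 2, 50)
        z = 9.0 - (6.12 - np.sqrt(6.12**2 - x**2))  # frowning arc
        assert fit_circle(x, z).radius == pytest.approx(-6.12, rel=1e-9)

    def test_collinear_points_return_flat_sentinel(self):
        c = fit_circle(np.linspace(0, 5, 20), np.full(20, 1.3))
        assert c.is_flat

    def test_monte_carlo_recovery_with_5um_noise(self):
        """200 points, radius 7.47 mm, aperture +-3 mm, 5 um noise: the fit
        recovers the radius within 0.05 mm (mean over repeats) and with
        < 0.5% bias."""
        rng = np.random.default_rng(42)
        radii = []
        for _ in range(30):
            x = np.linspace(-3, 3, 200)
            z = 7.47 - np.sqrt(7.47**2 - x**2) + rng.normal(0, 5e-3, x.size)
            radii.append(fit_circle(x, z).radius)
        radii = np.asarray(radii)
        assert abs(radii.mean() - 7.47) < 0.05
        assert abs(radii.mean() / 7.47 - 1) < 0.005

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            fit_circle([0.0, 1.0], [1.0, 0.0])


def analytic_traces(phantom, xs, arm_geometry=None):
    tr = optical_path_traces(phantom, xs, arm_geometry)
    return {
        lbl: BoundaryTrace(lbl, xs, tr[lbl],
                           np.full(xs.size, SOURCE_AUTO, np.uint8))
        for lbl in ORDERED_SURFACES
    }


class TestRefractionCorrect:
    def test_unit_indices_identity(self):
        media = MediaStack(n_cornea=1.0, n_aqueous=1.0, n_lens=1.0)
        ph = build_phantom(media=media)
        xs = np.linspace(-1.9, 1.9, 120)
        traces = analytic_traces(ph, xs)
        corrected = refraction_correct(traces, media)
        for lbl in ORDERED_SURFACES:
            np.testing.assert_allclose(corrected[lbl][1], traces[lbl].depth,
                                       atol=1e-12)

    def test_flat_layers_reduce_to_index_division(self):
        media = MediaStack()
        ph = build_phantom(rac=1e9, rpc=1e9, ral=1e9, rpl=1e9)
        xs = np.linspace(-1.5, 1.5, 60)
        corrected = refraction_correct(analytic_traces(ph, xs), media)
        cct = corrected["cornea-posterior"][1] - corrected["cornea-anterior"][1]
        np.testing.assert_allclose(cct, 0.55, atol=1e-9)  # 0.763 optical / 1.387

    def test_full_phantom_recovers_geometry_within_tolerance(self, phantom):
        xs = np.linspace(-5.2, 5.2, 600)
        corrected = refraction_correct(analytic_traces(phantom, xs), phantom.media)
        res = compute_biometry(corrected)
        gt = phantom.ground_truth
        for field, tol in (("rac", 0.02), ("rpc", 0.02), ("ral", 0.02), ("rpl", 0.02)):
            assert abs(getattr(res, field) / getattr(gt, field) - 1) < tol

    def test_round_trip_reproduces_optical_paths_within_1um(self, phantom):
        """The key correctness oracle: correct the forward model's optical
        traces, rebuild the geometry, re-run the forward model, and compare."""
        xs = np.linspace(-5.2, 5.2, 400)
        traces = analytic_traces(phantom, xs)
        corrected = refraction_correct(traces, phantom.media)
        rebuilt = build_phantom(
            cct=_apex(corrected, "cornea-posterior") - _apex(corrected, "cornea-anterior"),
            acd=_apex(corrected, "lens-anterior") - _apex(corrected, "cornea-posterior"),
            clt=_apex(corrected, "lens-posterior") - _apex(corrected, "lens-anterior"),
            rac=abs(fit_circle(*corrected["cornea-anterior"]).radius),
            rpc=abs(fit_circle(*corrected["cornea-posterior"]).radius),
            ral=abs(fit_circle(*corrected["lens-anterior"]).radius),
            rpl=abs(fit_circle(*corrected["lens-posterior"]).radius),
        )
        forward = optical_path_traces(rebuilt, xs)
        for lbl in ORDERED_SURFACES:
            a, b = forward[lbl], traces[lbl].depth
            m = np.isfinite(a) & np.isfinite(b)
            rms = np.sqrt(np.mean((a[m] - b[m]) ** 2))
            assert rms < 1e-3, f"{lbl}: {rms * 1e3:.2f} um"


def _apex(corrected, lbl):
    xs, zs = corrected[lbl]
    return _apex_depth(xs, zs, 1.5)


class TestTraceBoundaries:
    def test_manual_overrides_honored_exactly(self, small_bscan_set, arm_geometry,
                                              system3, source):
        from asoct import fuse_pair, max_scan_depth

        b1, b2 = small_bscan_set
        zmax = max_scan_depth(source.center_wavelength, system3.delta_lambda)
        fused = fuse_pair(b1, b2, arm_geometry, z_max=zmax, rotation_span=0.0)
        overrides = [("cornea-anterior", -2.0, 0.777), ("cornea-anterior", 1.0, 0.555)]
        traces = trace_boundaries(
            fused, exclude_halfwidth=10, strip_halfwidth_alines=20,
            manual_overrides=overrides,
        )
        tr = traces["cornea-anterior"]
        for x_mm, d_mm in ((-2.0, 0.777), (1.0, 0.555)):
            col = int(np.argmin(np.abs(tr.lateral - x_mm)))
            assert tr.depth[col] == d_mm

    def test_lens_traces_confined_to_pupil(self, small_bscan_set, arm_geometry,
                                           phantom, system3, source):
        from asoct import fuse_pair, max_scan_depth

        b1, b2 = small_bscan_set
        zmax = max_scan_depth(source.center_wavelength, system3.delta_lambda)
        fused = fuse_pair(b1, b2, arm_geometry, z_max=zmax, rotation_span=0.0)
        traces = trace_boundaries(fused, exclude_halfwidth=10,
                                  strip_halfwidth_alines=20)
        # trace coordinates are A-line entry positions; corneal refraction
        # lets rays entering up to ~1.3x the pupil radius reach the lens
        for lbl in ("lens-anterior", "lens-posterior"):
            xs = traces[lbl].lateral[traces[lbl].valid]
            assert np.max(np.abs(xs)) < phantom.pupil_radius * 1.4
        assert np.max(np.abs(traces["cornea-anterior"].lateral[
            traces["cornea-anterior"].valid])) > 3.0


class TestFitSigmoid:
    def test_constant_series_returns_zero_amplitude(self):
        t = np.linspace(0, 3.72, 31)
        fit = fit_sigmoid(t, np.full(31, 3.38))
        assert fit.amplitude == 0.0
        assert fit.baseline == pytest.approx(3.38)

    def test_self_recovery_at_protocol_sampling(self):
        """31 samples over 3.72 s with 5 um noise recover the generating
        parameters within 15% (amplitude, k) and 0.1 s (t0)."""
        truth = SigmoidParams(3.38, -0.09, 1.5, 8.0)
        t = np.arange(31) / 8.3
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(10):
            y = truth.value(t) + rng.normal(0, 5e-3, t.size)
            fit = fit_sigmoid(t, y, seed=1)
            errs.append((abs(fit.amplitude / truth.amplitude - 1),
                         abs(fit.k / truth.k - 1), abs(fit.t0 - truth.t0)))
        amp_err, k_err, t0_err = np.mean(errs, axis=0)
        assert amp_err < 0.15
        assert k_err < 0.15
        assert t0_err < 0.1

    def test_time_reversal_flips_amplitude_sign(self):
        truth = SigmoidParams(3.38, -0.09, 1.5, 8.0)
        t = np.arange(31) / 8.3
        y = truth.value(t)
        fwd = fit_sigmoid(t, y)
        rev = fit_sigmoid(t, y[::-1].copy())
        assert np.sign(fwd.amplitude) == -np.sign(rev.amplitude)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DomainError):
            fit_sigmoid([0, 1, 2], [1.0, 2.0, 3.0])
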