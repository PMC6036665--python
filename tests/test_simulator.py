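"""Forward model: ray tracing, interferogram synthesis, B-scan pairs."""

import numpy as np
import pytest

from asoct import (
    ArmGeometry,
    DomainError,
    MediaStack,
    build_phantom,
    default_phantom,
    simulate_bscan_pair,
    synthesize_interferogram,
    trace_reflectors,
)
from asoct.phantom import CORNEA_POSTERIOR, IRIS_PLANE, LENS_POSTERIOR


def reflector_map(phantom, x, arm_geometry=None, arm=1):
    return {r.label: r for r in trace_reflectors(phantom, x, arm_geometry, arm)}


class TestTraceReflectors:
    def test_corneal_optical_thickness_on_axis(self, phantom):
        r = reflector_map(phantom, 0.0)
        assert r[CORNEA_POSTERIOR].opd == pytest.approx(0.55 * 1.387, abs=1e-9)

    def test_unit_indices_give_geometric_depths(self):
        media = MediaStack(n_cornea=1.0, n_aqueous=1.0, n_lens=1.0)
        ph = build_phantom(media=media)
        r = reflector_map(ph, 1.0)
        for label in ("cornea-anterior", "cornea-posterior", "lens-anterior"):
            surf = ph.surface(label)
            assert r[label].opd == pytest.approx(
                surf.apex_z + float(surf.sag(1.0)), abs=1e-9
            )

    def test_arm2_is_arm1_minus_offset(self, phantom):
        arm = ArmGeometry(opd_offset=11.0, arm1_z0=0.0)
        r1 = reflector_map(phantom, 0.3, arm, arm=1)
        r2 = reflector_map(phantom, 0.3, arm, arm=2)
        for label in r1:
            assert r2[label].opd == pytest.approx(r1[label].opd - 11.0, abs=1e-12)

    def test_iris_annulus_only_outside_pupil(self, phantom):
        assert IRIS_PLANE not in reflector_map(phantom, 0.5)
        assert IRIS_PLANE in reflector_map(phantom, 3.0)

    def test_lens_invisible_beyond_pupil(self, phantom):
        r = reflector_map(phantom, 4.0)
        assert "lens-anterior" not in r
        assert LENS_POSTERIOR not in r

    def test_amplitudes_attenuated_by_overlying_interfaces(self, phantom):
        r = reflector_map(phantom, 0.0)
        ca = phantom.surface("cornea-anterior").reflectivity
        cp = phantom.surface(CORNEA_POSTERIOR).reflectivity
        assert r["cornea-anterior"].amplitude == pytest.approx(np.sqrt(ca))
        assert r[CORNEA_POSTERIOR].amplitude == pytest.approx(np.sqrt(cp) * (1 - ca))

    def test_out_of_extent_rejected(self, phantom):
        with pytest.raises(DomainError):
            trace_reflectors(phantom, 8.0)


class TestSynthesizeInterferogram:
    def test_dark_sample_returns_source_spectrum(self, mini_config, source):
        ig = synthesize_interferogram([], mini_config, source)
        np.testing.assert_allclose(
            ig.intensities, source.spectral_density(ig.wavelength_axis), atol=1e-14
        )

    def test_conjugate_depths_are_indistinguishable(self, mini_config, source):
        plus = synthesize_interferogram([(2.0, 0.05)], mini_config, source)
        minus = synthesize_interferogram([(-2.0, 0.05)], mini_config, source)
        np.testing.assert_allclose(plus.intensities, minus.intensities, atol=1e-14)

    def test_noise_free_output_independent_of_seed(self, mini_config, source):
        a = synthesize_interferogram([(2.0, 0.05)], mini_config, source, seed=1)
        b = synthesize_interferogram([(2.0, 0.05)], mini_config, source, seed=99)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_noisy_output_reproducible_given_seed(self, mini_config, source, quiet_noise):
        a = synthesize_interferogram([(2.0, 0.05)], mini_config, source, quiet_noise, seed=5)
        b = synthesize_interferogram([(2.0, 0.05)], mini_config, source, quiet_noise, seed=5)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_deep_reflector_warns_of_aliasing(self, mini_config, source):
        with pytest.warns(UserWarning, match="aliasing"):
            synthesize_interferogram([(30.0, 0.05)], mini_config, source)

    def test_detected_energy_matches_captured_fraction(self, system2, source):
        from asoct import effective_source_window

        ig = synthesize_interferogram([], system2, source)
        dl = system2.delta_lambda
        detected = float(ig.intensities.sum()) * dl
        total = source.sigma * np.sqrt(2 * np.pi)  # unit-peak Gaussian area
        frac = effective_source_window(system2, source)[2]
        assert detected / total == pytest.approx(frac, rel=1e-3)


class TestBScanPair:
    def test_same_seed_bit_identical(self, phantom, mini_config, source, arm_geometry):
        kw = dict(n_alines=32, seed=3)
        a1, a2 = simulate_bscan_pair(phantom, mini_config, source, arm_geometry, **kw)
        b1, b2 = simulate_bscan_pair(phantom, mini_config, source, arm_geometry, **kw)
        np.testing.assert_array_equal(a1.interferograms, b1.interferograms)
        np.testing.assert_array_equal(a2.interferograms, b2.interferograms)

    def test_aline_spacing_covers_lateral_extent(self, phantom, mini_config, source,
                                                 arm_geometry):
        f1, _ = simulate_bscan_pair(
            phantom, mini_config, source, arm_geometry, n_alines=64, noise=None
        )
        dx = np.diff(f1.lateral_axis)
        np.testing.assert_allclose(dx, 14.0 / 64, rtol=1e-12)

    def test_central_stripe_saturates(self, phantom, mini_config, source, arm_geometry):
        f1, _ = simulate_bscan_pair(
            phantom, mini_config, source, arm_geometry, n_alines=64, noise=None,
            full_well=4.0,
        )
        center = f1.interferograms[32]
        edge = f1.interferograms[4]
        assert center.max() == pytest.approx(4.0)
        assert edge.max() < 4.0

    def test_mirror_symmetric_phantom_gives_symmetric_arms(self, mini_config, source):
        """A reflector plane equidistant from both zero-delay planes must look
        identical to the two arms (the forward model's arm symmetry)."""
        media = MediaStack(n_cornea=1.0, n_aqueous=1.0, n_lens=1.0)
        ph = build_phantom(
            cct=1.0, acd=2.0, clt=2.0, rac=1e9, rpc=1e9, ral=1e9, rpl=1e9, media=media
        )
        # arm planes symmetric about the central (lens-anterior) plane at z=3
        arm = ArmGeometry(opd_offset=6.0, arm1_z0=0.0)
        f1, f2 = simulate_bscan_pair(
            ph, mini_config, source, arm, n_alines=16, noise=None,
            specular_artifact=False,
        )
        # flat plane at z=3 sits at +3 for arm 1 and -3 for arm 2
        r1 = reflector_map(ph, 0.0, arm, 1)["lens-anterior"].opd
        r2 = reflector_map(ph, 0.0, arm, 2)["lens-anterior"].opd
        assert r1 == pytest.approx(-r2)

    def test_minimum_alines_enforced(self, phantom, mini_config, source, arm_geometry):
        with pytest.raises(DomainError):
            simulate_bscan_pair(phantom, mini_config, source, arm_geometry, n_alines=1)
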