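import numpy as np
import pytest

from asoct import (
    NoiseParams,
    SourceSpectrum,
    SpectrometerConfig,
    default_phantom,
    recommended_arm_geometry,
    system_preset,
)


@pytest.fixture(scope="session")
def source():
    return SourceSpectrum()


@pytest.fixture(scope="session")
def system2():
    return system_preset("system2")


@pytest.fixture(scope="session")
def system1():
    return system_preset("system1")


@pytest.fixture(scope="session")
def system3():
    return system_preset("system3")


@pytest.fixture(scope="session")
def mini_config():
    """Small detector for fast unit tests; same dispersion as the presets."""
    return SpectrometerConfig(name="mini", camera="CCD", n_pixels=512, max_line_rate=1e3)


@pytest.fixture(scope="session")
def phantom():
    return default_phantom()


@pytest.fixture(scope="session")
def arm_geometry(phantom):
    return recommended_arm_geometry(phantom)


@pytest.fixture(scope="session")
def quiet_noise():
    """Faint read noise establishing a constant, physical noise floor."""
    return NoiseParams(read_noise_std=1e-4, shot_photons=0.0)


@pytest.fixture(scope="session")
def small_bscan_set(phantom, system3, source, arm_geometry):
    """One reduced-scale simulated/reconstructed frame pair, shared by the
    fusion and biometry tests (simulation dominates the cost)."""
    from asoct import reconstruct_frame, simulate_bscan_pair

    f1, f2 = simulate_bscan_pair(
        phantom, system3, source, arm_geometry, n_alines=384, seed=7
    )
    b1 = reconstruct_frame(f1, system3, source)
    b2 = reconstruct_frame(f2, system3, source)
    return b1, b2
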