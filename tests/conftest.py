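import numpy as np
import pytest

from tensiomap.simulate import SceneParams, simulate_scene

PX = 0.5  # µm, matches the generator default


@pytest.fixture(scope="session")
def study_scene():
    """One rendered scene at the default study conditions (snr=10)."""
    params = SceneParams(seed=5)
    truth, image = simulate_scene(params)
    return truth, image


@pytest.fixture(scope="session")
def noiseless_scene():
    """Same geometry rendered without PSF blur or noise."""
    params = SceneParams(seed=5, snr=np.inf, psf_sigma_px=0.0)
    truth, image = simulate_scene(params)
    return truth, image


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
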