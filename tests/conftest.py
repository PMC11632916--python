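import numpy as np
import pytest

from photogel import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ru_sps_noiseless():
    preset = simulate.preset_with(simulate.RHEO_PRESETS["RU_SPS"], noise_sd=0.0)
    return simulate.generate_time_sweep(preset, n_replicates=1, seed=0)[0]


@pytest.fixture(scope="session")
def monolayer_soft():
    return simulate.generate_monolayer_image(simulate.MONOLAYER_PRESETS["soft"], seed=7)
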