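import numpy as np
import pytest

from gutephys import SyntheticConfig, UnitSpec, build_tetrode_layout


@pytest.fixture(scope="session")
def default_layout():
    """The reference device: 7 tetrodes, 50/250 µm spacings, 4 markers."""
    return build_tetrode_layout()


@pytest.fixture(scope="session")
def single_tetrode():
    return build_tetrode_layout(n_tetrodes=1, n_markers=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_config(single_tetrode):
    """Small noise-only config for fast session-level tests."""
    return SyntheticConfig(layout=single_tetrode, fs=10_000.0, duration_s=10.0,
                           noise_sd_uv=5.0, seed=7)
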