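import numpy as np
import pytest

from specfuse.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_eem_config():
    """Small noiseless trilinear cube config (no scatter amplitudes matter
    when the generator is called with include_scatter=False)."""
    return SyntheticConfig(
        n_samples_per_class=4,
        n_replicates=1,
        noise_sd=0.0,
        em_grid=(250.0, 530.0, 2.0),
        rng_seed=7,
    )


@pytest.fixture
def small_nmr_config():
    return SyntheticConfig(
        n_samples_per_class=3,
        n_replicates=2,
        noise_sd=0.0,
        ppm_step=0.005,
        rng_seed=11,
    )
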