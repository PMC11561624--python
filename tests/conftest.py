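from dataclasses import replace

import numpy as np
import pytest

from crystalgate.signals import TimeSeries
from crystalgate.synthetic import PCA_PH_PRESETS, gen_pca_ph


@pytest.fixture(scope="session")
def kp_noise_free():
    """Noise-free kombucha–proteinoid composite traces (pCa, pH)."""
    params = replace(PCA_PH_PRESETS["kp_composite"],
                     pca_noise_sd=0.0, ph_noise_sd=0.0)
    return gen_pca_ph(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fair_coin_series(rng):
    """Balanced random binary-valued series on a 1 s grid."""
    n = 10_000
    bits = rng.integers(0, 2, n).astype(float)
    return TimeSeries(np.arange(n, dtype=float), bits,
                      channel_label="coin")
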