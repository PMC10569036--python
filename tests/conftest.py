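import numpy as np
import pandas as pd
import pytest

from turbofp.synthdata import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def clean_cfg() -> SimConfig:
    """Noise-free panel: linear response, no dropout, no blank signal."""
    return SimConfig(
        n_compounds=40,
        noise_sd_area=0.0,
        blank_level=0.0,
        dropout_prob=0.0,
        ionized_fraction=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_panel(clean_cfg):
    return simulate_panel(clean_cfg)


@pytest.fixture(scope="session")
def rank3_logk() -> pd.DataFrame:
    """A larger noise-free rank-3 log K database for imputation tests."""
    cfg = SimConfig(n_compounds=150, seed=23)
    return simulate_panel(cfg).logk


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
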