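import numpy as np
import pandas as pd
import pytest

from netgex import synthdata as sd
from netgex._types import EffectSpec


@pytest.fixture(scope="session")
def small_atlas():
    return sd.generate_atlas(21, seed=11)


@pytest.fixture(scope="session")
def atlas30():
    return sd.generate_atlas(30, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def null_effect():
    return EffectSpec(network_pairs=[], delta=0.0)


def smooth_target_map(atlas: pd.DataFrame, length: float = 25.0, seed: int = 0) -> pd.Series:
    """Spatially smooth (squared-exponential GP) regional map for PLS tests."""
    rng = np.random.default_rng(seed)
    cents = atlas[["x", "y", "z"]].to_numpy()
    d2 = ((cents[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-d2 / (2 * length**2)) + 1e-8 * np.eye(len(atlas))
    return pd.Series(
        np.linalg.cholesky(K) @ rng.standard_normal(len(atlas)),
        index=atlas["region_id"].to_numpy(),
    )
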