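import numpy as np
import pytest

from gazeblind import (ModelParams, SyntheticPairSpec, make_change_pair,
                       make_catch_pair, partition_grid)
from gazeblind.simulate import FoveationCache


@pytest.fixture(scope="session")
def small_params():
    """Fast settings: 144x108 px pairs (12x9 grid), 15 s trials."""
    return ModelParams(trial_bins=600)


@pytest.fixture(scope="session")
def small_pair():
    spec = SyntheticPairSpec(width=144, height=108, change_radius=12,
                             change_center=(40, 40), contrast=0.8,
                             change_kind="appearance", n_objects=6, seed=5)
    return make_change_pair(spec)


@pytest.fixture(scope="session")
def small_catch_pair():
    spec = SyntheticPairSpec(width=144, height=108, change_radius=12,
                             n_objects=6, seed=6)
    return make_catch_pair(spec)


@pytest.fixture(scope="session")
def small_cache(small_pair, small_params):
    grid = partition_grid(small_pair.width, small_pair.height,
                          small_params.patch_px)
    return FoveationCache(small_pair, grid, small_params)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
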