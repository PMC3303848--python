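import numpy as np
import pytest

from bnbmla.mcmc import MCMCConfig, mc3_run
from bnbmla.scoring import ScoreConfig
from helpers import make_dataset


@pytest.fixture(scope="session")
def planted_chain_dataset():
    """x0 -> x1 -> y chain plus an independent ternary noise variable."""
    rng = np.random.default_rng(11)
    n = 200
    x0 = rng.integers(0, 2, n)
    x1 = (x0 ^ (rng.random(n) < 0.15)).astype(int)
    y = (x1 ^ (rng.random(n) < 0.15)).astype(int)
    noise = rng.integers(0, 3, n)
    return make_dataset({"x0": x0, "x1": x1, "noise": noise, "y": y},
                        targets=("y",))


@pytest.fixture(scope="session")
def small_stream(planted_chain_dataset):
    """A modest seeded run reused by aggregation and invariant tests."""
    cfg = MCMCConfig(burn_in=5_000, n_steps=60_000, n_chains=2,
                     feature_eval_interval=1, seed=7)
    return mc3_run(planted_chain_dataset, ScoreConfig(), cfg)
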