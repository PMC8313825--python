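import numpy as np
import pytest

from lncpair import PairSignatureModel, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Default-scale synthetic cohort (100 tumor / 20 normal), fixed seed."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def fitted(small_dataset):
    """One fitted cascade on the small cohort, shared across tests."""
    ds = small_dataset
    model = PairSignatureModel(ds.expression, ds.clinical, ds.annotation, ds.immune_genes)
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_survival(rng, n, beta=0.0, x=None, censor=0.3):
    """Simple exponential survival draw for unit tests (times continuous, tie-free)."""
    if x is None:
        x = rng.standard_normal(n)
    t = rng.exponential(1.0, n) / np.exp(beta * x)
    if censor > 0:
        c = rng.exponential(1.0 / censor, n)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
    else:
        times, events = t, np.ones(n, dtype=int)
    return times + 1e-9, events, x
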