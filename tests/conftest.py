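import numpy as np
import pytest

import synscreen as s


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(rng, n, scale=1.0):
    M = rng.normal(0, scale, size=(n, n))
    return 0.5 * (M + M.T)


def rank2_benchmark(seed):
    """Rank-2 modular 100x100 system with noise at 10% of the signal SD,
    an informative similarity kernel and a 20%-observed split."""
    kw = dict(n=100, k=2, hub_strength=1.0, hub_fraction=0.0, threshold=-np.inf)
    base = s.simulate_system(noise_sd=0.0, seed=seed, **kw)
    sig_sd = np.std(base.M_true[np.triu_indices(100, k=1)])
    system = s.simulate_system(noise_sd=0.1 * sig_sd, seed=seed, **kw)
    Q = s.informative_q(system, fidelity=1.0, seed=seed)
    D, held = s.holdout_split(system.M_true, 0.2, seed=seed + 10_000,
                              target_ids=system.target_ids)
    return system, Q, D, held


@pytest.fixture(scope="session")
def benchmark():
    return rank2_benchmark(seed=3)


@pytest.fixture(scope="session")
def hub_system():
    """Modular system with hubs, the screening-benchmark configuration."""
    system = s.simulate_system(n=120, k=5, target_prevalence=0.05, seed=11)
    Q = s.informative_q(system, fidelity=1.0, seed=11)
    return system, Q
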