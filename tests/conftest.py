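import numpy as np
import pytest

from efmdfs.oracle_fixtures import (chain_network, diamond_network,
                                    gen_random_network, lossy_diamond_network,
                                    toy_synthetic_network)

BACKENDS = ["glpk", "highs"]


@pytest.fixture(scope="session")
def chain():
    return chain_network()


@pytest.fixture(scope="session")
def diamond():
    return diamond_network()


@pytest.fixture(scope="session")
def lossy_diamond():
    return lossy_diamond_network()


@pytest.fixture(scope="session")
def toy():
    return toy_synthetic_network()


def random_networks(n, seed=0, max_rxns=16, max_dof=5, density=0.4):
    """Deterministic stream of feasible random test networks."""
    rng = np.random.default_rng(seed)
    made = 0
    attempt = 0
    while made < n:
        dof = int(rng.integers(2, max_dof + 1))
        r = int(rng.integers(dof + 3, max_rxns + 1))
        attempt += 1
        try:
            net = gen_random_network(r - dof, r, density,
                                     seed=int(rng.integers(2 ** 31)))
        except RuntimeError:
            continue
        made += 1
        yield net
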