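import numpy as np
import pytest

from netattack.network import MarketNetwork


@pytest.fixture
def toy_net() -> MarketNetwork:
    """3 ties: {(b1,V1),(b2,V1),(b1,V2)}; V3 and b3 are isolates."""
    return MarketNetwork(
        buyers={"b1", "b2", "b3"},
        vendors={"V1", "V2", "V3"},
        ties={("b1", "V1"), ("b2", "V1"), ("b1", "V2")},
        reputation={"V1": 10.0, "V2": 5.0, "V3": 0.0},
    )


def random_bipartite(rng: np.random.Generator, n_buyers=6, n_vendors=4, density=0.4) -> MarketNetwork:
    buyers = [f"b{i}" for i in range(n_buyers)]
    vendors = [f"v{j}" for j in range(n_vendors)]
    mask = rng.random((n_buyers, n_vendors)) < density
    ties = {(buyers[i], vendors[j]) for i, j in zip(*np.nonzero(mask))}
    rep = {v: float(rng.exponential(10.0)) for v in vendors}
    return MarketNetwork(set(buyers), set(vendors), ties, rep)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
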