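import numpy as np
import pytest

from wealthnet.alaam_stats import AlaamModel, Effect, EffectSpec
from wealthnet.network_build import MultilevelNetwork, TieInfo, affiliate
from wealthnet.synthetic_data import GeneratorConfig, generate_population


def make_toy_net() -> MultilevelNetwork:
    """12 households in 2 regions; sparse with one triangle and a bridge."""
    ties = {
        (0, 1): TieInfo(2, 1),
        (1, 2): TieInfo(1, 1),
        (0, 2): TieInfo(0, 1),
        (2, 3): TieInfo(4, 1),
        (3, 4): TieInfo(2, 1),
        (4, 5): TieInfo(1, 1),
        (5, 6): TieInfo(0, 1),
        (6, 7): TieInfo(3, 2),
        (7, 8): TieInfo(1, 1),
        (8, 9): TieInfo(2, 1),
        (9, 10): TieInfo(0, 1),
        (10, 11): TieInfo(1, 1),
        (3, 7): TieInfo(1, 1),
    }
    net = MultilevelNetwork(households=list(range(12)), ties=ties)
    return affiliate(net, {h: (0 if h < 6 else 1) for h in range(12)})


@pytest.fixture(scope="session")
def toy_net() -> MultilevelNetwork:
    return make_toy_net()


@pytest.fixture(scope="session")
def toy_model(toy_net) -> AlaamModel:
    spec = EffectSpec(
        [
            Effect("density_household"),
            Effect("density_region"),
            Effect("contagion_same_region"),
        ]
    )
    return AlaamModel(toy_net, spec)


@pytest.fixture(scope="session")
def small_pop():
    """Generated population at reduced scale shared across test modules."""
    cfg = GeneratorConfig(n_households=300, n_regions=8, seed=7)
    return generate_population(cfg)


def random_multilevel_net(n_h=30, n_r=3, p=0.08, seed=0) -> MultilevelNetwork:
    rng = np.random.default_rng(seed)
    ties = {}
    for i in range(n_h):
        for j in range(i + 1, n_h):
            if rng.random() < p:
                ties[(i, j)] = TieInfo(float(rng.integers(0, 8)), int(rng.integers(1, 3)))
    net = MultilevelNetwork(households=list(range(n_h)), ties=ties)
    return affiliate(net, {h: int(rng.integers(n_r)) for h in range(n_h)})
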