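import numpy as np
import pytest

from gemvuln import (
    DEFAULT_BOUND,
    FixtureSpec,
    build_model,
    figure_like_nets,
    make_fixture,
)


def fixture_spec_for_seed(seed: int) -> FixtureSpec:
    """Small deterministic spec family used by the property suites."""
    return FixtureSpec(
        n_metabolites=8,
        n_reactions=9 + seed % 4,  # <= 12 reactions
        reversible_fraction=0.25 * (seed % 3),
        n_parallel_paths=1 + seed % 2,
        include_dem=seed % 2 == 0,
        include_dead=seed % 3 == 0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def net1():
    return figure_like_nets()[0]


@pytest.fixture(scope="session")
def net2():
    return figure_like_nets()[1]


@pytest.fixture(scope="session")
def parallel_net():
    """Two independent paths of capacities 3 and 4 into biomass."""
    return make_fixture(
        FixtureSpec(n_parallel_paths=2, path_capacities=(3.0, 4.0), n_reactions=5,
                    n_metabolites=3, seed=0)
    )


@pytest.fixture(scope="session")
def chain_net():
    """Single import-limited chain: exchange [0, 10] into biomass."""
    return build_model(
        {
            "ex": ({"A": 1.0}, 0.0, 10.0),
            "rg": ({"A": -1.0}, 0.0, DEFAULT_BOUND),
        },
        objective="rg",
    )


@pytest.fixture(scope="session")
def random_models():
    return [make_fixture(fixture_spec_for_seed(s)) for s in range(1, 21)]


@pytest.fixture(scope="session")
def zero_growth_net():
    """Feasible model whose growth reaction is clamped to zero flux."""
    return build_model(
        {
            "ex": ({"A": 1.0}, 0.0, 10.0),
            "sink": ({"A": -1.0}, 0.0, DEFAULT_BOUND),
            "rg": ({"A": -1.0}, 0.0, 0.0),
        },
        objective="rg",
    )


@pytest.fixture()
def random_small_model():
    """6 metabolites x 8 reactions with random sparse stoichiometry."""
    rng = np.random.default_rng(42)
    mets = [f"m{i}" for i in range(6)]
    reactions = {}
    for j in range(8):
        stoich = {}
        for i in rng.choice(6, size=rng.integers(1, 4), replace=False):
            stoich[mets[i]] = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
        lo, hi = sorted(rng.choice([-1000.0, 0.0, 0.0, 1000.0], size=2))
        reactions[f"r{j}"] = (stoich, lo, hi)
    return build_model(reactions)
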