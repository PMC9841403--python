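import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from geopriorkit.geomodel import (DispersalModel, GeoAlphabet, PriorSpec,
                                  default_alphabet)
from geopriorkit.synth_fixtures import FixtureScenario, make_scenario
from geopriorkit.treedata_io import TipAreas
from geopriorkit import parse_newick


@pytest.fixture(scope="session")
def quartet_tree():
    return parse_newick("((A:0.3,B:0.7):0.4,(C:0.2,D:0.9):0.1);")


@pytest.fixture(scope="session")
def quartet_tips():
    alphabet = GeoAlphabet(("p", "q", "r"))
    return TipAreas({"A": "p", "B": "q", "C": "r", "D": "p"}, alphabet)


@pytest.fixture(scope="session")
def small_scenario():
    """30-tip, 3-area dataset simulated under mu = 0.5."""
    return make_scenario(FixtureScenario(n_tips=30, k=3, mu=0.5, seed=42))


@pytest.fixture(scope="session")
def default_fixture():
    """The default study fixture: 50 tips, 3 areas, mu = 0.5."""
    return make_scenario(FixtureScenario(seed=42))


@pytest.fixture(scope="session")
def toy_1d():
    """Small 1-D problem (10 tips, 2 areas, rates fixed) for marginal
    likelihoods: tree, tips, base model, prior on mu."""
    tree, tips, _ = make_scenario(FixtureScenario(n_tips=10, k=2, mu=0.5, seed=21))
    base = DispersalModel(default_alphabet(2), True, np.ones(1), mu=1.0)
    prior = PriorSpec("exponential", "mu", {"rate": 1.0})
    return tree, tips, base, prior


def fixed_rates_priors(mu_spec: PriorSpec) -> dict:
    return {"mu": mu_spec,
            "rel_rates": PriorSpec("fixed", "rel_rates", {"value": 1.0})}
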