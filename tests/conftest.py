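import numpy as np
import pytest

from flashkin import (GeneratorConfig, build_cygb_scheme, preset_rates)
from flashkin.scheme import NetworkModel, RateSet, StateSpec, Transition


@pytest.fixture(scope="session")
def wt_model():
    return build_cygb_scheme("wt", site5_exit=True, hexa_site6=True)


@pytest.fixture(scope="session")
def he7q_model():
    return build_cygb_scheme("HE7Q", site5_exit=True, hexa_site6=False)


@pytest.fixture(scope="session")
def wt_rates():
    return preset_rates("wt_solution")


@pytest.fixture
def two_state_model():
    """A -> B irreversible, B absorbing."""
    return NetworkModel(
        (StateSpec("A", "docked"), StateSpec("B", "bound")),
        (Transition("A", "B", "k"),),
    )


@pytest.fixture
def chain3_model():
    """A <-> B -> C with C absorbing (purely first order)."""
    return NetworkModel(
        (StateSpec("A", "docked"), StateSpec("B", "docked"),
         StateSpec("C", "bound")),
        (Transition("A", "B", "k1"), Transition("B", "A", "k2"),
         Transition("B", "C", "k3")),
    )


@pytest.fixture
def chain3_rates():
    return RateSet({"k1": 3.3e5, "k2": 1.2e4, "k3": 7.7e6})


def random_wt_rates(rng, model):
    """Log-uniform positive rates spanning 1e0..1e8 s^-1 for a scheme."""
    vals = {sym: 10.0 ** rng.uniform(0, 8) for sym in model.rate_symbols}
    return RateSet(vals)
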