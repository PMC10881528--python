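import numpy as np
import pytest

from pcabm import LatticeConfig, ParameterSet, ScenarioConfig, get_preset


@pytest.fixture
def small_lattice():
    return LatticeConfig(width=25, height=25)


@pytest.fixture
def preset_r():
    return get_preset("R1881")


@pytest.fixture
def preset_d():
    return get_preset("DMSO")


@pytest.fixture
def quiet_params():
    """All action probabilities zero: nothing ever happens."""
    return ParameterSet(
        TUpprol=0.0, TUpmig=0.0, TUpdeath=0.0, TUpres=0.0,
        TUpprolres=0.0, TUpmigres=0.0, TUpmaxres=50,
        M1pkill=0.0, M1pmig=0.0, M2pkill=0.0, M2pmig=0.0, M2TUadd=0.0,
        Fpprol=0.0, Fpmig=0.0, Fpdeath=0.0)


def make_config(counts, lattice=None, ticks=5, condition="R1881",
                resistant_fraction=0.0):
    return ScenarioConfig(name="test", lattice=lattice or LatticeConfig(25, 25),
                          counts=counts, condition=condition, ticks=ticks,
                          resistant_fraction=resistant_fraction)
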