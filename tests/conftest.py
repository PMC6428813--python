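import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from dispersim.config import NoiseModel, PenaltyModel, RunConfig, ThermalParams
from dispersim.cytometry import SpilloverMatrix


@pytest.fixture
def default_config():
    return RunConfig()


@pytest.fixture
def example_spillover():
    """The worked-example spillover panel: five ratios, the sixth (B42 into
    the E111 gate) negligible and absent."""
    return SpilloverMatrix(
        strains=("B42", "E310", "E111"),
        ratios={
            ("B42", "E310"): 0.0169,
            ("E310", "B42"): 0.135,
            ("E310", "E111"): 0.007,
            ("E111", "B42"): 0.127,
            ("E111", "E310"): 0.064,
        },
        capture_fractions={"B42": 1.0, "E310": 1.0, "E111": 1.0})


@pytest.fixture
def constant_temperature_config():
    """Config whose vessels start exactly at their set-points, so vessel
    temperatures are constant in time and the lag+exponential closed form
    is the exact solution at zero dispersal."""
    thermal = ThermalParams(initial_temperatures=(25.0, 37.0, 42.0))
    return RunConfig(thermal=thermal, penalty=PenaltyModel.none())


@pytest.fixture
def zero_growth_config():
    from dispersim.config import default_growth_table
    gt = default_growth_table()
    gt["r_growth_per_min"] = 0.0
    return RunConfig(growth_table=gt, penalty=PenaltyModel.none())


@pytest.fixture
def quiet_noise():
    return NoiseModel.none()
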