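import numpy as np
import pytest

from dendrisnip import grow_population, growth_defaults, make_fixture
from dendrisnip.growth import AngleModel, CompartmentSpec, GrowthParams
from dendrisnip.regions import Cone


@pytest.fixture
def ybranch():
    return make_fixture("ybranch")


@pytest.fixture
def binary2():
    return make_fixture("binary2")


@pytest.fixture
def chain10():
    return make_fixture("chain10")


@pytest.fixture
def shollfork():
    return make_fixture("shollfork")


def mini_growth_params(alpha: float = 0.15, seed=None) -> GrowthParams:
    """Small, fast trees (~50-150 segments) for property tests."""
    comp = CompartmentSpec(
        label="dendrite",
        n_primaries=1,
        initial_radius=1.0,
        taper_rate=0.04,
        alpha_schedule={1: alpha, 2: alpha, 3: alpha},
        terminal_length_mean=8.0,
        bounding_volume=Cone(half_angle_deg=40.0, height=120.0),
    )
    return GrowthParams(
        neuron_class="GCL",
        angle_model=AngleModel(half_angle_mean_deg=28.0, half_angle_sd_deg=7.0, wobble_sd_deg=3.0),
        compartments=[comp],
        seed=seed,
    )


@pytest.fixture(scope="session")
def gcl_population():
    """The default 10-neuron GCL population at a fixed base seed."""
    return grow_population(growth_defaults("GCL"), 10, 20)


@pytest.fixture(scope="session")
def ca1_population():
    """The default 10-neuron CA1 population at a fixed base seed."""
    return grow_population(growth_defaults("CA1"), 10, 20)


@pytest.fixture(scope="session")
def gcl_neuron(gcl_population):
    return gcl_population[0]
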