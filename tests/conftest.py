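import numpy as np
import pytest

from breathvoc import SimConfig, simulate_study
from breathvoc.siftms import (
    CompoundSpec,
    InstrumentParams,
    ProductIonChannel,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A scaled-down cohort for fast unit tests."""
    return SimConfig(
        n_cancer=40, n_control_campus=30, n_control_hospital=15,
        n_bg_campus=10, n_bg_hospital=12,
        panel_size=24, disease_set_size=8, env_differential_set_size=8,
        sparse_set_size=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture(scope="session")
def default_study():
    """The study-sized simulation (148 cancer / 112+56 controls / 18+29 air)."""
    return simulate_study(SimConfig(seed=29))


@pytest.fixture
def instr() -> InstrumentParams:
    return InstrumentParams(reaction_time=5e-3, dilution_factor=1.0,
                            carrier_number_density=2.46e19)


@pytest.fixture
def two_compound_library() -> list[CompoundSpec]:
    ch_a = ProductIonChannel("voc_a", "H3O+", 59, 2.5e-9, 1.0)
    ch_b = ProductIonChannel("voc_b", "NO+", 88, 3.0e-9, 0.8)
    return [
        CompoundSpec("voc_a", "acetone-like", "ketones", (ch_a,)),
        CompoundSpec("voc_b", "pentanal-like", "aldehydes", (ch_b,)),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
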