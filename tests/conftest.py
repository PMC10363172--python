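import numpy as np
import pytest

from depotnca import (
    DEFAULT_POPULATION,
    MetaboliteParams,
    PKParameters,
    PopulationParams,
    paper_design,
)


@pytest.fixture(scope="session")
def design():
    return paper_design()


@pytest.fixture(scope="session")
def typical():
    return DEFAULT_POPULATION.typical


@pytest.fixture(scope="session")
def single_depot():
    """One-depot parameters with ka well above ke (no flip-flop)."""
    return PKParameters(
        clearance_over_F=2.0, volume_over_F=86.6, ka_fast=0.5, ka_slow=0.01,
        frac_fast=1.0,
    )


@pytest.fixture(scope="session")
def metabolite_params():
    return MetaboliteParams(fm=0.3, volume_m_over_F=80.0, ke_m=0.05)


@pytest.fixture(scope="session")
def noise_free_population(typical):
    return PopulationParams(typical=typical, bsv_cv={}, residual_cv=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
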