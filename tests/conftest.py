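import numpy as np
import pytest

from phagefilm.bacteria import BacterialPopulation, StrainTable
from phagefilm.params import (BacteriaParams, ResistanceMode, SpaceConfig, Strain,
                              default_config)
from phagefilm.space import build_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_space():
    """A 10x10-node 2D lattice with 3-um nodes."""
    return SpaceConfig(x_max_um=30.0, y_max_um=30.0, dl_um=3.0)


@pytest.fixture
def small_grid(small_space):
    return build_grid(small_space)


@pytest.fixture
def bact_params():
    return BacteriaParams()


@pytest.fixture
def strain_table(bact_params):
    strains = (
        Strain(id="susceptible", resistance_mode=ResistanceMode.SUSCEPTIBLE,
               cost_c=0.0, interaction_rate_I=0.09),
        Strain(id="resistant", resistance_mode=ResistanceMode.SURFACE,
               cost_c=0.05, interaction_rate_I=0.09),
        Strain(id="abortive", resistance_mode=ResistanceMode.ABORTIVE,
               cost_c=0.05, interaction_rate_I=0.09),
        Strain(id="neutralizing", resistance_mode=ResistanceMode.PHAGE_NEUTRALIZING,
               cost_c=0.05, interaction_rate_I=0.09),
        Strain(id="surface_halting", resistance_mode=ResistanceMode.SURFACE,
               cost_c=0.05, interaction_rate_I=0.09, halt_on_contact=True),
    )
    return StrainTable(strains, BacteriaParams())


def make_population(strain_table, dim=2, m_s=1e-12):
    return BacterialPopulation(strain_table, dim, m_s)


@pytest.fixture
def population(strain_table):
    return make_population(strain_table)


@pytest.fixture
def table1_config():
    return default_config()
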