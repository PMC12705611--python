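import numpy as np
import pytest

from phenoloop.synthetic import (
    DoseDesign,
    WAVELENGTH_GRID,
    brown_endmember,
    default_params,
    green_endmember,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def wl():
    return WAVELENGTH_GRID.copy()


@pytest.fixture(scope="session")
def endmembers(wl):
    return green_endmember(wl), brown_endmember(wl)


@pytest.fixture(scope="session")
def round1_study():
    """Default 7-dose x 6-replicate study, reused by read-only tests."""
    return simulate_experiment(DoseDesign.round1(), default_params(), seed=1)


@pytest.fixture(scope="session")
def harvest(round1_study):
    from phenoloop.loop import harvest_table

    return harvest_table(round1_study)
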