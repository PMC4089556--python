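import numpy as np
import pytest

from nrf2pk import (DosingSchedule, NrfParameters, PKParameters,
                    SyntheticScenario, simulate_coupled, simulate_pk)
from nrf2pk.units import DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def mode_pk():
    """Published posterior-mode disposition parameters."""
    return PKParameters()


@pytest.fixture(scope="session")
def mode_nrf():
    """Published posterior-mode pathway parameters."""
    return NrfParameters()


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(seed=101)


@pytest.fixture(scope="session")
def pk_traj_5(mode_pk, geometry):
    return simulate_pk(mode_pk, geometry, DosingSchedule(dose_uM=5.0))


@pytest.fixture(scope="session")
def pk_traj_15(mode_pk, geometry):
    return simulate_pk(mode_pk, geometry, DosingSchedule(dose_uM=15.0))


@pytest.fixture(scope="session")
def coupled_traj_5(mode_nrf, mode_pk, geometry):
    return simulate_coupled(mode_nrf, mode_pk, geometry,
                            DosingSchedule(dose_uM=5.0))


@pytest.fixture(scope="session")
def coupled_traj_15_60d(mode_nrf, mode_pk, geometry):
    return simulate_coupled(mode_nrf, mode_pk, geometry,
                            DosingSchedule(dose_uM=15.0, n_doses=60))
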