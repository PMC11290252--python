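import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import copevolve as cv
from copevolve.mortality import MortalityParams
from copevolve.selection import SelectionEngine

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bio_params():
    return cv.BioParams()


@pytest.fixture(scope="session")
def year7_forcing():
    """Single early-bloom year (year-7 analog) repeated, with lookahead."""
    return cv.assemble_sequence([cv.station_mike_year(7)])


@pytest.fixture(scope="session")
def year7_store(year7_forcing, bio_params):
    return cv.build_lookup(year7_forcing, p=bio_params)


@pytest.fixture(scope="session")
def year7_engine(year7_store, year7_forcing):
    return SelectionEngine(year7_store, year7_forcing, MortalityParams())


@pytest.fixture(scope="session")
def decade_forcing():
    return cv.assemble_sequence(cv.station_mike_decade())


@pytest.fixture(scope="session")
def decade_store(decade_forcing, bio_params):
    return cv.build_lookup(decade_forcing, p=bio_params)


@pytest.fixture(scope="session")
def ia_engine(decade_store, decade_forcing):
    return SelectionEngine(decade_store, decade_forcing, MortalityParams())


def make_flat_trajectory(n_days=100, phase=2, start_day=1, eggs=None, starved=False):
    """Hand-built trajectory for sampler tests: constant phase, no biology."""
    phases = np.full(n_days, phase, dtype=np.int8)
    return cv.Trajectory(
        key=cv.TrajectoryKey(1, 50, 110),
        days=np.arange(start_day, start_day + n_days, dtype=np.int32),
        phase=phases,
        structure_c=np.full(n_days, 6.5),
        lipid_c=np.zeros(n_days),
        eggs=np.zeros(n_days, dtype=np.int32) if eggs is None else np.asarray(eggs, dtype=np.int32),
        deep=(phases == 4) | (phases == 5),
        starvation_day=start_day + n_days - 1 if starved else None,
        viable=True,
    )


@pytest.fixture(scope="session")
def constant_forcing():
    """Constant SST at the mortality reference temperature, ample food."""
    n = 3 * 365
    return cv.ForcingSeries(
        food=np.full((n, 4), 1.5), sst=np.full(n, 9.0), n_years=1
    )
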