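"""Shared fixtures: small simulated datasets and hand-built tables."""

import numpy as np
import pytest

from quantal import (
    GridSpec,
    ObservationSet,
    QuantalParams,
    SimulationDesign,
    simulate_observations,
)
from quantal.stats import GroupSample


@pytest.fixture(scope="session")
def small_obs() -> ObservationSet:
    """50 sweeps over 2 conditions from a 3-site synapse (seeded)."""
    design = SimulationDesign(
        params=QuantalParams.from_cv(3, 0.5, 0.3),
        condition_ps=(0.3, 0.7),
        sweeps_per_condition=25,
        noise_sd=0.1,
        seed=7,
    )
    return simulate_observations(design)


@pytest.fixture(scope="session")
def reduced_grid_spec() -> GridSpec:
    """Coarse grid small enough for brute-force cross-checks."""
    return GridSpec(n_max=4, q_resolution=16, gamma_resolution=8)


def balanced_icc_table() -> GroupSample:
    """3 units x 4 observations constructed so MSB=30, MSW=6, k=4.

    Unit means are offset by (-a, 0, +a) with 2*a^2 = 15 so the
    between-unit sum of squares is 4*15 = 60 (MSB = 60/2 = 30); each
    unit's deviations (0, 0, -3, 3) give a within sum of squares of
    3*18 = 54 (MSW = 54/9 = 6).  ICC(1,1) = (30-6)/(30+3*6) = 0.5.
    """
    a = np.sqrt(7.5)
    values = []
    units = []
    for u, mean in enumerate([-a, 0.0, a]):
        values.extend(mean + np.array([0.0, 0.0, -3.0, 3.0]))
        units.extend([u] * 4)
    return GroupSample(values=np.array(values), unit_id=np.array(units))


@pytest.fixture
def icc_fixture() -> GroupSample:
    return balanced_icc_table()
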