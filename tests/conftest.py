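"""Shared fixtures: small synthetic sessions reused across the suite.

Sessions are generated once per test run (session scope) at a reduced
10-minute length so the full suite stays fast while still containing every
planted event type and enough samples for the statistical stages.
"""

import numpy as np
import pytest

from pagstates.core import AssayGeometry, PoseTrack
from pagstates.pipeline import prepare_session
from pagstates.synthio import SimulationConfig, simulate_cohort, simulate_session


SMALL = dict(session_length=600.0, n_cells=40, seed=11)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return simulate_cohort(sim_config)


@pytest.fixture(scope="session")
def epm_session(cohort):
    return cohort.epm


@pytest.fixture(scope="session")
def rat_session(cohort):
    return cohort.rat


@pytest.fixture(scope="session")
def toy_session(cohort):
    return cohort.toy


@pytest.fixture(scope="session")
def epm_prepared(epm_session):
    return prepare_session(epm_session)


@pytest.fixture(scope="session")
def rat_prepared(rat_session):
    return prepare_session(rat_session)


@pytest.fixture(scope="session")
def toy_prepared(toy_session):
    return prepare_session(toy_session)


def straight_pose(xy, geometry, fps=30.0, rat_xy=None):
    """PoseTrack from a bare centroid trajectory (keypoints collapsed onto
    the centroid, so centroid/head/tailbase kinematics coincide)."""
    xy = np.asarray(xy, dtype=float)
    kp = {k: xy.copy() for k in ("nose", "ear_l", "ear_r", "tailbase")}
    if rat_xy is not None:
        rat_xy = np.asarray(rat_xy, dtype=float)
        if rat_xy.ndim == 1:
            rat_xy = np.tile(rat_xy, (len(xy), 1))
        kp["rat"] = rat_xy
    return PoseTrack(kp, fps, geometry)


@pytest.fixture
def make_pose():
    return straight_pose
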