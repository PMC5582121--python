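import warnings

import numpy as np
import pytest

from apmoments.cell_models import PacingProtocol, SolverConfig, toy_model
from apmoments.database import (
    ParameterBox,
    SimulationDatabase,
    TimeSeriesSpec,
    build_database,
    sobol_sample,
)

# noise-skew warnings from filter_feasible etc. are expected in several tests
warnings.filterwarnings("ignore", category=RuntimeWarning, module="apmoments")


@pytest.fixture(scope="session")
def toy():
    return toy_model()


@pytest.fixture(scope="session")
def protocol():
    return PacingProtocol(n_prepace=0)


@pytest.fixture(scope="session")
def solver_cfg():
    return SolverConfig()


@pytest.fixture(scope="session")
def toy_db_2p(toy, protocol):
    """Small 2-parameter toy time-series database shared across tests."""
    box = ParameterBox.cube(["g_dep", "g_decay"], 0.5, 2.0)
    spec = TimeSeriesSpec(np.arange(30.0, 300.5, 2.0))
    coll = sobol_sample(box, 2 ** 9)
    return build_database(toy, box, coll, protocol, spec)


def identity_database(n_points: int = 1024) -> SimulationDatabase:
    """1-D database whose observable is the parameter itself (u = θ on [0,1])."""
    box = ParameterBox(["x"], [0.0], [1.0])
    coll = sobol_sample(box, n_points)
    return SimulationDatabase(
        box=box,
        collocation=coll,
        observables=coll.points.copy(),
        observable_index=["u"],
        valid_mask=np.ones(coll.n_c, dtype=bool),
        eval_counter=0,
    )


@pytest.fixture()
def id_db():
    return identity_database()
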