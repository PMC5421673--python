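import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from emgstiff import dynamics as dyn
from emgstiff import kinematics as kin
from emgstiff import simulation as sim


@pytest.fixture(scope="session")
def geometry() -> kin.LowerLimbGeometry:
    return kin.LowerLimbGeometry()


@pytest.fixture(scope="session")
def tables(geometry) -> dict[str, kin.MuscleGeometryTable]:
    return kin.build_geometry_tables(geometry)


@pytest.fixture(scope="session")
def model(geometry, tables) -> dyn.LowerExtremityModel:
    return dyn.LowerExtremityModel(geometry=geometry, tables=tables)


@pytest.fixture(scope="session")
def experiment(model) -> dict:
    """Full default in-silico estimation run, shared across tests."""
    return sim.run_estimation_experiment(model=model, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
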