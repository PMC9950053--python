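import numpy as np
import pytest

from zlap.pose_io import default_schedule
from zlap.synthetic_data import PHENOTYPES, simulate_trajectory
from zlap.well_grid import WellCircle


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def well():
    return WellCircle(cx=200.0, cy=200.0, radius=75.0, row=0, col=0, well_id="A1")


@pytest.fixture(scope="session")
def control_larva(schedule, well):
    """One full-length control-phenotype recording (ground truth + noisy poses)."""
    return simulate_trajectory(PHENOTYPES["control"], schedule, n_frames=1800,
                               seed=42, well=well, phenotype="control")


@pytest.fixture(scope="session")
def control_features(control_larva, schedule):
    """Canonical 33-column feature table of the control larva."""
    from zlap.kinematics import build_feature_table

    return build_feature_table({"A1": control_larva.pose}, [control_larva.well],
                               schedule, plate_id="P1")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
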