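import numpy as np
import pytest

from spemlab import (
    ScreenGeometry,
    TaskConfig,
    Trajectory,
    generate_target_trajectory,
    load_table1_fixture,
)


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def target():
    """One generated default-task stimulus with its event log."""
    return generate_target_trajectory(TaskConfig(seed=1))


@pytest.fixture(scope="session")
def fixture_table():
    return load_table1_fixture()


@pytest.fixture
def straight_line():
    """A 120-sample straight trajectory moving right at ~4.17 px/frame."""
    t = np.arange(120)
    pos = np.column_stack([100 + t * 250 / 60.0, np.full(120, 200.0)])
    return Trajectory(pos)
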