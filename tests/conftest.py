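import numpy as np
import pytest

from skittles import (EXP1_PROFILE, build_grid, compute_tolerance, load_preset)


@pytest.fixture(scope="session")
def exp1():
    return load_preset("exp1")


@pytest.fixture(scope="session")
def exp2():
    return load_preset("exp2")


@pytest.fixture(scope="session")
def exp1_cal():
    return load_preset("exp1_calibrated")


@pytest.fixture(scope="session")
def exp2_cal():
    return load_preset("exp2_calibrated")


@pytest.fixture(scope="session")
def exp1_grid(exp1_cal):
    """Full-resolution execution space for the calibrated first workspace."""
    return build_grid(exp1_cal, 360, 360)


@pytest.fixture(scope="session")
def exp1_tmap(exp1_grid):
    return compute_tolerance(exp1_grid, EXP1_PROFILE)


@pytest.fixture(scope="session")
def exp2_grid(exp2_cal):
    return build_grid(exp2_cal, 360, 360)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
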