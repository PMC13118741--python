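import numpy as np
import pytest

import pemosi


@pytest.fixture(scope="session")
def params() -> pemosi.ModelParams:
    return pemosi.ModelParams()


@pytest.fixture(scope="session")
def one_cycle_sequential() -> pemosi.Regimen:
    return pemosi.build_regimen("sequential", interval_h=48.0, n_cycles=1)


@pytest.fixture(scope="session")
def one_cycle_control() -> pemosi.Regimen:
    return pemosi.build_regimen("control", n_cycles=1)


@pytest.fixture(scope="session")
def control_trajectory(params, one_cycle_control) -> pemosi.Trajectory:
    return pemosi.simulate(one_cycle_control, params)


@pytest.fixture(scope="session")
def sequential_trajectory(params, one_cycle_sequential) -> pemosi.Trajectory:
    return pemosi.simulate(one_cycle_sequential, params)


def assert_close(a, b, rtol, msg=""):
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    assert np.allclose(a, b, rtol=rtol), (
        f"{msg} expected {b}, got {a} (rtol {rtol})")
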