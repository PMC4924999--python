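import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import axobeat as ab

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wt_params():
    return ab.mechanical_params("chlamy_wt")


@pytest.fixture(scope="session")
def curvature_resp(wt_params):
    r = ab.MotorResponse("curvature", chi=19.8, beta=-6.5j)
    r.chi_b = ab.critical_basal_impedance(wt_params, r)
    return r


@pytest.fixture(scope="session")
def wt_curvature_solution(wt_params, curvature_resp):
    return ab.solve_dynamic_mode(wt_params, curvature_resp, n_grid=201)


@pytest.fixture(scope="session")
def sliding_resp(wt_params):
    r = ab.MotorResponse("sliding", chi=-12.2 - 1.1j)
    r.chi_b = ab.critical_basal_impedance(wt_params, r)
    return r


@pytest.fixture(scope="session")
def model_series(wt_params, curvature_resp):
    return ab.make_model_series(
        wt_params, curvature_resp, noise_angle=0.02, seed=11, n_frames=1500
    )


@pytest.fixture(scope="session")
def model_decomp(model_series):
    return ab.decompose(model_series)


@pytest.fixture(scope="session")
def planewave_series():
    spec = ab.SyntheticSpec.from_preset("chlamy_wt", seed=3, n_frames=1500)
    return ab.make_planewave_series(spec)


@pytest.fixture(scope="session")
def planewave_decomp(planewave_series):
    return ab.decompose(planewave_series)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
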