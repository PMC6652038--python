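import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import virhopf as vh

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scenarios() -> dict[str, vh.Scenario]:
    return {sc.name: sc for sc in vh.builtin_scenarios()}


@pytest.fixture(scope="session")
def case2a(scenarios):
    return scenarios["case2a"].params


@pytest.fixture(scope="session")
def case1b(scenarios):
    return scenarios["case1b"].params


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240717)


def numeric_jacobian_tau0(params: vh.ModelParameters, state, h: float = 1e-6) -> np.ndarray:
    """Finite-difference Jacobian of the tau=0 vector field at *state*.

    The lagged w-argument is folded into the w column (e^{-lambda*tau} = 1),
    which is the matrix whose eigenvalues the tau=0 characteristic quartic
    must reproduce.
    """
    state = np.asarray(state, float)

    def field(x):
        return np.asarray(vh.rhs(x, x[1], params))

    jac = np.zeros((4, 4))
    for j in range(4):
        step = h * max(1.0, abs(state[j]))
        xp = state.copy()
        xm = state.copy()
        xp[j] += step
        xm[j] = max(xm[j] - step, 0.0)
        jac[:, j] = (field(xp) - field(xm)) / (xp[j] - xm[j])
    return jac
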