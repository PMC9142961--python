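import numpy as np
import pytest
from scipy.integrate import solve_ivp

from alphachain import decay
from alphachain.synthetic import CounterModel


@pytest.fixture(scope="session")
def chain():
    """Default 3-member chain (At-217 in instantaneous equilibrium)."""
    return decay.ac225_chain()


@pytest.fixture(scope="session")
def full_chain():
    """Full 4-member chain including At-217."""
    return decay.ac225_chain(full=True)


@pytest.fixture
def counter():
    return CounterModel()


def ode_activities(chain, initial_activities: dict, times):
    """Independent stiff-ODE oracle for chain activities.

    Integrates the atom-balance ODEs with scipy's Radau solver at tight
    tolerances and returns an array of activities, shape (len(times),
    n_members).  Entirely independent of the closed-form Bateman path.
    """
    lam = chain.lambdas
    n0 = np.array([initial_activities.get(name, 0.0) for name in chain.names]) / lam

    def rhs(_, n):
        dn = -lam * n
        dn[1:] += np.asarray(chain.branching) * lam[:-1] * n[:-1]
        return dn

    times = np.asarray(times, float)
    sol = solve_ivp(rhs, (0.0, float(times.max())), n0, method="Radau",
                    t_eval=times, rtol=1e-11, atol=1e-16)
    assert sol.success
    return (sol.y * lam[:, None]).T
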