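import numpy as np
import pytest
from hypothesis import settings

from oculopharm.engine import GenerativeModel
from oculopharm.task import TaskConfig, build_model

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def task_model() -> GenerativeModel:
    return build_model(TaskConfig())


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


def single_factor_toy():
    """3-state / 3-outcome / 3-step single-factor chain with a soft likelihood
    and a sticky transition; exact smoothing is enumerable by brute force."""
    A = np.array([[0.7, 0.2, 0.1],
                  [0.2, 0.6, 0.3],
                  [0.1, 0.2, 0.6]])
    B = np.zeros((3, 3, 2))
    B[:, :, 0] = np.array([[0.8, 0.1, 0.1],
                           [0.1, 0.8, 0.1],
                           [0.1, 0.1, 0.8]])
    B[:, :, 1] = np.roll(np.eye(3), 1, axis=0)
    D = np.array([0.5, 0.3, 0.2])
    policies = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    return GenerativeModel(A=[A], B=[B], C=[np.zeros(3)], D=[D],
                           policies=policies, T=3, controllable_factor=0)


def brute_force_marginals(model: GenerativeModel, outcomes, policy):
    """Exact smoothing marginals by enumerating every joint state sequence."""
    import itertools

    sizes = model.state_sizes
    T = model.T
    nf = model.n_factors
    cf = model.controllable_factor
    margs = [np.zeros((T, s)) for s in sizes]
    total = 0.0
    per_factor_states = [list(itertools.product(range(s), repeat=T)) for s in sizes]
    for combo in itertools.product(*per_factor_states):
        # combo[f][tau] = state of factor f at time tau
        p = 1.0
        for f in range(nf):
            p *= model.D[f][combo[f][0]]
            for tau in range(1, T):
                u = policy[tau - 1] if f == cf else 0
                p *= model.B[f][combo[f][tau], combo[f][tau - 1], u]
        for tau, obs in enumerate(outcomes):
            joint = tuple(combo[f][tau] for f in range(nf))
            for m, o in enumerate(obs):
                p *= model.A[m][(o,) + joint]
        total += p
        for f in range(nf):
            for tau in range(T):
                margs[f][tau, combo[f][tau]] += p
    return [m / total for m in margs], total
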