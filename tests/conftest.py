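import numpy as np
import pytest

from aortasurv.msm_markov import N_STATES, NonHomogeneousMCM
from aortasurv.synthetic_cohort import SyntheticConfig, generate_cohort


def random_model(rng: np.random.Generator, n_steps: int = 6,
                 interval_length: float = 6.0) -> NonHomogeneousMCM:
    """Random valid chain: upper-triangular row-stochastic, D absorbing."""
    matrices = []
    for _ in range(n_steps):
        m = np.zeros((N_STATES, N_STATES))
        for i in range(N_STATES - 1):
            # modest off-diagonal mass so trajectories stay interesting
            off = rng.dirichlet(np.ones(N_STATES - 1 - i)) * rng.uniform(0.0, 0.3)
            m[i, i + 1:] = off
            m[i, i] = 1.0 - off.sum()
        m[-1, -1] = 1.0
        matrices.append(m)
    return NonHomogeneousMCM(interval_length=interval_length, matrices=tuple(matrices))


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(n_patients=400, seed=7)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)
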