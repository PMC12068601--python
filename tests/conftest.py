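import numpy as np
import pytest

import dynindep as di


@pytest.fixture(scope="session")
def var2():
    """Small known stable VAR(2)."""
    A = np.zeros((2, 3, 3))
    A[0] = [[0.5, 0.1, 0.0], [0.2, 0.4, -0.1], [0.0, 0.3, 0.3]]
    A[1] = [[-0.2, 0.0, 0.1], [0.0, 0.1, 0.0], [0.1, 0.0, -0.2]]
    return di.VarModel(A, np.eye(3))


@pytest.fixture(scope="session")
def worked_example():
    """The 9-channel order-8 planted-structure model and its SS embedding."""
    var = di.make_worked_example_var(seed=1)
    return var, di.var_to_ss(var)


@pytest.fixture(scope="session")
def planted_toy():
    """Minimal planted-source system: rotating pair {1, 2} plus observer."""
    var = di.make_planted_source_var(seed=0)
    return var, di.var_to_ss(var)


@pytest.fixture(scope="session")
def random_ss_models():
    """A pool of random stable, minimum-phase innovations SS models."""
    rng = np.random.default_rng(7)
    models = []
    while len(models) < 20:
        m = rng.integers(2, 5)
        N = rng.integers(3, 6)
        A = rng.standard_normal((m, m)) * 0.8 / np.sqrt(m)
        C = rng.standard_normal((N, m))
        K = rng.standard_normal((m, N)) * 0.25 / np.sqrt(N)
        L = rng.standard_normal((N, N)) / np.sqrt(N)
        V = L @ L.T + 0.5 * np.eye(N)
        try:
            models.append(di.SSModel(A, C, K, V))
        except ValueError:
            continue
    return models
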