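import numpy as np
import pytest

from memorient.synthetic import (KineticScheme, EmissionSpec,
                                 simulate_hidden_jump_process,
                                 emit_orientation)


@pytest.fixture(scope="session")
def two_state_scheme():
    """Symmetric 2-state scheme, k = 0.01 /us in both directions."""
    Q = np.array([[-0.01, 0.01], [0.01, -0.01]])
    return KineticScheme(rate_matrix=Q, state_labels=["a", "b"])


@pytest.fixture(scope="session")
def well_separated_emission():
    """Two basins far apart in both angles (negligible overlap)."""
    return EmissionSpec(centers=[(40.0, -90.0), (140.0, 90.0)],
                        sigmas=[(8.0, 15.0), (8.0, 15.0)],
                        state_labels=["a", "b"])


@pytest.fixture(scope="session")
def small_two_state_run(two_state_scheme, well_separated_emission):
    """Frame labels plus emitted angles for a modest 2-state run."""
    paths = simulate_hidden_jump_process(two_state_scheme, duration_us=3000.0,
                                         dt_ns=15.0, n_replicas=4, seed=101)
    trajs = [emit_orientation(p, well_separated_emission, seed=500 + i)
             for i, p in enumerate(paths)]
    return paths, trajs
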