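import numpy as np
import pytest
from hypothesis import settings

from richconn import CohortConfig, ConnectivityMatrix, generate_cohort, load_default_atlas

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def matrix_from_edges(n, edges, subject_id=""):
    """Build a ConnectivityMatrix from (i, j, weight) triples."""
    w = np.zeros((n, n))
    for i, j, wt in edges:
        w[i, j] = w[j, i] = wt
    return ConnectivityMatrix.from_array(w, subject_id=subject_id)


def complete_matrix(n, weight=1.0):
    return ConnectivityMatrix.from_array(weight * (np.ones((n, n)) - np.eye(n)))


@pytest.fixture(scope="session")
def atlas():
    return load_default_atlas()


@pytest.fixture(scope="session")
def triangle():
    return matrix_from_edges(3, [(0, 1, 0.5), (1, 2, 0.5), (0, 2, 0.1)])


@pytest.fixture(scope="session")
def star5():
    """Star with 4 leaves, unit weights; center is node 0."""
    return matrix_from_edges(5, [(0, i, 1.0) for i in range(1, 5)])


@pytest.fixture(scope="session")
def path3():
    return matrix_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 1)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 6+6 / 12 HC cohort with default topology, for pipeline tests."""
    cfg = CohortConfig(seed=3, n_ani=6, n_nonhand=6, n_hc=12)
    return generate_cohort(cfg)
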