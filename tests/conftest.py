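import numpy as np
import pytest

from cpmreserve import GeneratorConfig, fit_cr_residual, generate_cohort
from cpmreserve.cpm import edge_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate planted-signal cohort shared across tests (fast: 40 nodes)."""
    cfg = GeneratorConfig(n_subjects=150, n_nodes=40, n_pos_edges=6,
                          n_neg_edges=6, gamma=0.45, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_fit(small_cohort):
    """(edge matrix, node ids), reserve residuals for the shared cohort."""
    X, node_ids = edge_matrix(small_cohort.matrices)
    res = fit_cr_residual(small_cohort.cohort)
    return X, node_ids, res


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
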