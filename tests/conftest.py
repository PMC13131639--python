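import numpy as np
import pytest
from hypothesis import settings

from synoclust import io_core, simulate

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bulk():
    """120-sample bulk cohort with strong planted 4-cluster structure."""
    params = simulate.BulkSimParams(
        n_samples=120, n_genes=800, markers_per_cluster=80, log2_effect=4,
        cluster_proportions=(0.29, 0.38, 0.27, 0.06), seed=11)
    matrix, meta = simulate.simulate_bulk(params)
    return matrix, meta


@pytest.fixture(scope="session")
def small_logcpm(small_bulk):
    matrix, meta = small_bulk
    return io_core.log_cpm(matrix), meta


@pytest.fixture(scope="session")
def small_sc():
    """Default 8-type single-cell simulation at reduced size."""
    return simulate.simulate_sc(simulate.ScSimParams(
        n_cells=1600, n_genes=600, seed=5))


@pytest.fixture(scope="session")
def small_spatial():
    return simulate.simulate_spatial(simulate.SpatialSimParams(
        n_cells=8000, seed=9))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, layer="raw_counts", gene_prefix="g",
                sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    return io_core.ExpressionMatrix(genes, samples, values, layer)
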