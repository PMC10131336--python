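import numpy as np
import pytest

from toplinegs.io_kinship import MarkerMatrix, compute_grm
from toplinegs.synthetic_data import SimConfig, simulate_genotypes, simulate_phenotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_marker_matrix(rng, n, p, missing_rate=0.0, inbred=False):
    freqs = rng.uniform(0.1, 0.5, size=p)
    if inbred:
        # mostly homozygous calls, het rate ~2%
        dos = 2.0 * rng.binomial(1, freqs, size=(n, p))
        het = rng.uniform(size=dos.shape) < 0.02
        dos = np.where(het, 1.0, dos)
    else:
        dos = rng.binomial(2, freqs, size=(n, p)).astype(float)
    miss = rng.uniform(size=dos.shape) < missing_rate
    return MarkerMatrix(
        [f"L{i}" for i in range(n)], [f"M{j}" for j in range(p)], dos, miss
    )


@pytest.fixture
def small_markers(rng):
    return random_marker_matrix(rng, 8, 40)


@pytest.fixture
def sim_bundle():
    """Complete genotypes + phenotypes + truth at a size fast enough for
    model-fitting unit tests."""
    cfg = SimConfig(n_lines=200, n_markers=400, n_qtl=60, h2=0.5, seed=7)
    M = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(M, cfg)
    return M, pheno, truth, cfg


@pytest.fixture
def sim_kinship(sim_bundle):
    M, pheno, truth, cfg = sim_bundle
    return compute_grm(M), pheno, truth
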