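import numpy as np
import pytest

import scellintegrate as sci


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down 3-batch simulation (400 cells/batch, 4 shared + 1 unique type)."""
    cfg = sci.SimConfig(
        cells_per_batch=400,
        seed=2,
        types_per_batch=[[0, 1, 2, 3], [0, 1, 2, 3], [0, 1, 2, 3, 4]],
        type_proportions=[[0.25] * 4, [0.25] * 4, [0.2] * 5],
    )
    return sci.simulate(cfg)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    matrix, _ = small_sim
    return sci.normalize(sci.filter_genes(matrix, 10))


@pytest.fixture(scope="session")
def benchmark():
    """The canonical 3-batch acceptance benchmark (6,000 cells, fixed seed)."""
    return sci.default_benchmark()


@pytest.fixture(scope="session")
def benchmark_integration(benchmark):
    matrix, _ = benchmark
    return sci.run_supervised_integration(matrix, sci.IntegrationConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
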