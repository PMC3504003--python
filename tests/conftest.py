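import numpy as np
import pytest

from divmat import (
    TRAITS,
    CovarianceMatrix,
    SimulationConfig,
    simulate_experiment,
    standardize_table,
)

#: published pooled divergence matrix of the four traits (variances on the
#: diagonal, covariances below; the fixture mirrors it symmetrically)
POOLED_D_VALUES = np.array(
    [
        [1.727, 0.464, 0.291, -0.002],
        [0.464, 0.881, 0.297, -0.049],
        [0.291, 0.297, 1.518, -0.682],
        [-0.002, -0.049, -0.682, 2.271],
    ]
)

#: the published eigenanalysis of that matrix
EXPECTED_EIGENVALUES = np.array([2.743, 1.984, 1.034, 0.637])
EXPECTED_PROPORTIONS = np.array([0.43, 0.31, 0.16, 0.10])
EXPECTED_LOADINGS = np.array(
    [
        [-0.231, -0.164, -0.537, 0.795],
        [0.822, 0.367, 0.144, 0.411],
        [-0.415, 0.128, 0.787, 0.438],
        [-0.315, 0.907, -0.267, -0.085],
    ]
)


@pytest.fixture(scope="session")
def pooled_D() -> CovarianceMatrix:
    return CovarianceMatrix(TRAITS, POOLED_D_VALUES, 60, "sample_of_means")


@pytest.fixture(scope="session")
def default_sim():
    """One default-size simulated experiment (60 lineages + ancestor)."""
    return simulate_experiment(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_sim():
    """A tiny experiment for expensive per-fit comparisons."""
    cfg = SimulationConfig(lineages_per_treatment=4, replicates_per_lineage=2, seed=7)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_std_table(small_sim):
    table, _ = small_sim
    return standardize_table(table.without_ancestor())


@pytest.fixture(scope="session")
def default_std_table(default_sim):
    table, _ = default_sim
    return standardize_table(table.without_ancestor())
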