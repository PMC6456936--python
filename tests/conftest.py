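import numpy as np
import pytest

from enigma import (
    CovariateTable,
    EnigmaParameters,
    FitConfig,
    OtuTable,
    SimulationConfig,
    generate_dataset,
    generate_parameters,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Two well-separated classes, one covariate; small but informative."""
    config = SimulationConfig(
        n_samples=60, n_taxa=12, n_classes=2, total_count=500, n_covariates=1, seed=7
    )
    truth = generate_parameters(config, seed=7)
    Y, X, z = generate_dataset(truth, config, seed=8)
    return Y, X, z, truth, config


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    from enigma import fit_map

    Y, X, z, truth, config = small_dataset
    return fit_map(Y, X, 2, FitConfig(seed=0))


@pytest.fixture
def toy_params():
    return EnigmaParameters(
        pi=np.array([0.6, 0.4]),
        gamma=np.array([[0.3, -0.2, 0.1], [-0.5, 0.4, 0.0]]),
        B=np.array([[0.2, -0.1, 0.05]]),
        sigma=1.0,
        tau=1.0,
    )


@pytest.fixture
def toy_tables():
    Y = OtuTable(counts=np.array([[3, 1, 2], [0, 4, 1]]))
    X = CovariateTable(design=np.array([[1.0], [0.0]]), sample_ids=Y.sample_ids)
    return Y, X
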