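import pytest

from hospavoid import CostEffectivenessModel, default_parameters


@pytest.fixture(scope="session")
def base_params():
    """Shipped base-case parameter set (usual care, intervention, economics)."""
    return default_parameters()


@pytest.fixture(scope="session")
def model():
    return CostEffectivenessModel.from_defaults()


@pytest.fixture(scope="session")
def base_results(model):
    return model.fit()


@pytest.fixture(scope="session")
def psa_1000(model):
    """One 1000-draw probabilistic sensitivity analysis, shared across tests."""
    return model.fit_psa(n_draws=1000, seed=0)
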