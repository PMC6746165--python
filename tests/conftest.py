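import pytest

from plastphen.features import feature_table, run_pca, screen_features
from plastphen.preprocess import assemble_matrix, average_runs, normalize_to_reference
from plastphen.synthetic import default_effects, generate_dataset, table2_design


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the bundled study layout with the default planted effects."""
    return generate_dataset(table2_design(), default_effects(), seed=12345)


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    ds = normalize_to_reference(default_dataset, "5wk_normal")
    return assemble_matrix(average_runs(ds))


@pytest.fixture(scope="session")
def default_pca(default_matrix):
    return run_pca(default_matrix)


@pytest.fixture(scope="session")
def default_features(default_matrix):
    return feature_table(default_matrix)


@pytest.fixture(scope="session")
def default_screening(default_features, default_pca):
    return screen_features(default_features, default_pca)
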