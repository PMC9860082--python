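import numpy as np
import pytest

import midmap as mm


@pytest.fixture(scope="session")
def small_atlas():
    """3-type, well-separated synthetic atlas shared across tests."""
    spec = mm.AtlasSpec(
        n_types=3, n_cells_per_type=100, n_genes=500, n_markers_per_type=20,
        marker_log2fc=3.0, seed=1,
    )
    adata, truth = mm.generate_atlas(spec)
    return spec, adata, truth


@pytest.fixture(scope="session")
def small_atlas_norm(small_atlas):
    _, adata, _ = small_atlas
    return mm.normalize_log_library(adata)


@pytest.fixture(scope="session")
def small_model(small_atlas, small_atlas_norm):
    _, adata, _ = small_atlas
    features = mm.select_features(
        small_atlas_norm.var_names, small_atlas_norm.var_names
    )
    model = mm.fit_classifier(
        small_atlas_norm, adata.obs["cell_type"], features, seed=0
    )
    return features, model


@pytest.fixture(scope="session")
def small_query(small_atlas):
    """50 pure type-1 cells followed by 50 cells mixing types 0 and 2."""
    _, _, truth = small_atlas
    w = np.vstack(
        [mm.one_hot_weights(50, 3, 1), mm.mixed_weights(50, 3, 0, 2)]
    )
    adata, qtruth = mm.generate_query(
        truth, mm.QuerySpec(program_weights=w, seed=2)
    )
    return adata, qtruth
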