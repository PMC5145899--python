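import numpy as np
import pandas as pd
import pytest

from coexatlas import AtlasSpec, ExpressionAtlas, generate_atlas
from coexatlas.preprocess import filter_variable_genes, log_transform


@pytest.fixture(scope="session")
def default_atlas_truth():
    """Default synthetic atlas with ground truth (seed 1)."""
    return generate_atlas(AtlasSpec(seed=1))


@pytest.fixture(scope="session")
def filtered_log_atlas(default_atlas_truth):
    atlas, _ = default_atlas_truth
    return log_transform(filter_variable_genes(atlas))


def make_atlas(values, scale_state="raw", prefix="G"):
    """Small helper: build an atlas from a plain 2-d list/array."""
    values = np.asarray(values, dtype=float)
    data = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"S{j}" for j in range(values.shape[1])],
    )
    return ExpressionAtlas(data=data, scale_state=scale_state)
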