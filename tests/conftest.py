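import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from gutliver import (CohortSpec, FeatureTable, LayerSpec, SampleMetadata,
                      generate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_counts():
    """2-layer-free toy: one bacterial count table, 3 samples."""
    values = pd.DataFrame(
        [[2, 1, 0], [2, 3, 0], [0, 0, 5]],
        index=["g1", "g2", "g3"], columns=["s1", "s2", "s3"],
    )
    return FeatureTable("bacteria", values, "counts")


@pytest.fixture
def toy_metadata():
    return SampleMetadata(pd.Series(
        {"s1": "Ctrl", "s2": "LC", "s3": "HCC"}))


def small_null_spec(seed, n_features=30, depth=5000):
    """All-null spec: no shifts, no stars, small depth for speed."""
    return CohortSpec(
        layer_specs=[
            LayerSpec("bacteria", n_features, depth=depth,
                      base_concentrations=np.full(n_features, 5.0)),
            LayerSpec("metabolite", n_features,
                      means=np.full(n_features, 100.0), sds=np.full(n_features, 20.0)),
        ],
        seed=seed,
    )


@pytest.fixture
def null_dataset():
    return generate_cohort(small_null_spec(seed=7))
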