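import numpy as np
import pytest

from emophys import pipeline, synthgen


@pytest.fixture(scope="session")
def small_records():
    """Two synthetic participants, one 20 s segment per emotion."""
    return synthgen.generate_dataset(2, 1, seed=42)


@pytest.fixture(scope="session")
def small_feature_table(small_records):
    """FeatureTable of the small dataset (8 segments x 136 features)."""
    return pipeline.records_to_features(small_records)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
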