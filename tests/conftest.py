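import numpy as np
import pytest

from harimages.synthetic import ACTIVITIES, SyntheticDatasetSpec, generate_dataset


@pytest.fixture(scope="session")
def small_stream():
    """2 users x 6 activities x 10 s at 20 Hz = 2400 samples."""
    spec = SyntheticDatasetSpec(n_users=2, segment_duration_s=10.0, seed=7)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def medium_stream():
    """3 users x 6 activities x 30 s: enough for several windows per segment."""
    spec = SyntheticDatasetSpec(n_users=3, segment_duration_s=30.0, seed=11)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def label_index():
    return {a: i for i, a in enumerate(ACTIVITIES)}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
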