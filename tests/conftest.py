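import numpy as np
import pytest

from dwtpet.synthetic_data import DoseLevel, build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 3-subject, 32x32 dataset with two dose levels, built once per session."""
    out = tmp_path_factory.mktemp("tiny_ds")
    manifest = build_dataset(
        out,
        n_subjects=3,
        dose_levels=[DoseLevel(0.25), DoseLevel(1.0)],
        shape=(32, 32),
        seed=7,
    )
    return out, manifest
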