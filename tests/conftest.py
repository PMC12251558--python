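import numpy as np
import pytest
from hypothesis import settings

from gpbr import features_from_manifest, loio_split
from gpbr.synthdata import generate_dataset

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def two_cue_data(tmp_path_factory):
    """Two-cue synthetic dataset, featurized: the mechanism-test bench.

    3 individuals x 5 classes x 8 clips of 6 s at 8 kHz; fold 0 of the
    leave-one-individual-out split serves as the train/test pair.
    """
    root = tmp_path_factory.mktemp("two_cue")
    manifest = generate_dataset(root, n_individuals=3,
                                class_mix={k: 8 for k in range(5)},
                                two_cue=True, seed=0)
    X, y = features_from_manifest(manifest)
    train_idx, test_idx = loio_split(manifest)[0]
    return {"manifest": manifest, "X": X, "y": y,
            "train_idx": train_idx, "test_idx": test_idx}


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Small default-profile dataset (imbalanced five behaviours)."""
    root = tmp_path_factory.mktemp("default_ds")
    manifest = generate_dataset(
        root, n_individuals=2,
        class_mix={"eating": 4, "resting": 6, "moving": 3, "nursing": 2,
                   "drinking": 2},
        seed=1)
    return {"root": root, "manifest": manifest}
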