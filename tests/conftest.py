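import numpy as np
import pytest

from pulsegate.dnn_models import S1Config, build_s1
from pulsegate.preprocessing import dataset_to_arrays
from pulsegate.synthetic import generate_dataset
from pulsegate.training import TrainingConfig, train

N_ENSEMBLE_SEEDS = 10


@pytest.fixture(scope="session")
def small_data():
    """A modest patient-structured train/test pair for cheap model tests."""
    tr = generate_dataset(10, 10, (2, 4), seed=301)
    te = generate_dataset(6, 6, (2, 4), seed=901)
    return {"train": dataset_to_arrays(tr), "test": dataset_to_arrays(te),
            "train_ds": tr, "test_ds": te}


@pytest.fixture(scope="session")
def study_data():
    """The study-condition synthetic sets: 100 training patients and a
    disjoint 40-patient test set, half PR / half PEA each."""
    tr = generate_dataset(50, 50, (2, 6), seed=2024)
    te = generate_dataset(20, 20, (2, 6), seed=7024)
    return {"train": dataset_to_arrays(tr), "test": dataset_to_arrays(te)}


@pytest.fixture(scope="session")
def trained_ensemble(study_data):
    """Ten S1{λ=2, M=8, L=5, α=0.1} models trained with the full recipe
    (75 epochs, batch 8) on the study training set, one per seed."""
    Xtr, ytr, ptr = study_data["train"]
    models = []
    for seed in range(N_ENSEMBLE_SEEDS):
        model = build_s1(S1Config(2, 8, 5, 0.1), input_len=Xtr.shape[1],
                         seed=seed)
        train(model, Xtr, ytr, ptr, TrainingConfig(), seed=seed)
        models.append(model)
    return models


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
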