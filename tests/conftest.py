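"""Shared fixtures: synthetic cohorts and trained study models.

The heavy objects (preprocessed cohorts, trained autoencoders) are
session-scoped and cached per seed so that module tests and the
acceptance suite share one training run per seed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)

from evlatent import ae as aemod
from evlatent import synth
from evlatent.preprocess import preprocess_set


@dataclasses.dataclass
class StudyRun:
    """One synthetic study realization: cohorts, matrices, trained model."""

    seed: int
    training_cohort: object
    clinical_cohort: object
    X_training: pd.DataFrame
    X_clinical: pd.DataFrame
    bin_grid: np.ndarray
    model: aemod.AEModel
    Z_training: pd.DataFrame
    Z_clinical: pd.DataFrame
    clinical_groups: np.ndarray


def _run_study(seed: int) -> StudyRun:
    training = synth.generate_cohort(synth.training_cohort_config(20, seed=seed))
    clinical = synth.generate_cohort(
        synth.clinical_cohort_config(seed=seed + 100),
        effect=synth.default_disease_effect(),
    )
    X_tr, _ = preprocess_set(training)
    X_cl, _ = preprocess_set(clinical)
    model = aemod.build_model(train_config=aemod.study_train_config(seed))
    aemod.train(model, pd.concat([X_tr, X_cl]))
    return StudyRun(
        seed=seed,
        training_cohort=training,
        clinical_cohort=clinical,
        X_training=X_tr,
        X_clinical=X_cl,
        bin_grid=np.asarray([float(c) for c in X_cl.columns]),
        model=model,
        Z_training=aemod.encode(model, X_tr),
        Z_clinical=aemod.encode(model, X_cl),
        clinical_groups=clinical.metadata["group"].to_numpy(),
    )


@pytest.fixture(scope="session")
def study_runs():
    """Factory with per-seed caching of full study realizations."""
    cache: dict[int, StudyRun] = {}

    def get(seed: int) -> StudyRun:
        if seed not in cache:
            cache[seed] = _run_study(seed)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def study(study_runs) -> StudyRun:
    return study_runs(0)


@pytest.fixture(scope="session")
def training_cohort(study):
    return study.training_cohort


@pytest.fixture(scope="session")
def processed_training(study) -> pd.DataFrame:
    return study.X_training


@pytest.fixture(scope="session")
def tiny_model() -> aemod.AEModel:
    """A small trained autoencoder for fast unit checks."""
    arch = aemod.AEArchitecture(input_dim=24, encoder_units=(16, 8), latent_dim=4)
    cfg = aemod.TrainConfig(seed=0, learning_rate=1e-3, dropout_rate=0.0,
                            val_fraction=0.0, patience=300, max_epochs=300)
    rng = np.random.default_rng(0)
    basis = rng.normal(size=(3, 24))
    X = rng.normal(size=(40, 3)) @ basis + 0.05 * rng.normal(size=(40, 24))
    model = aemod.build_model(arch, cfg)
    return aemod.train(model, X)
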