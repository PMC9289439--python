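"""Shared fixtures: synthetic campaigns and trained pipelines.

The expensive fixtures (20-epoch classifier, proxy-loss embedding) are
session-scoped and shared between the module tests and the acceptance
tests, so each training pipeline runs exactly once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import fieldmark as fm
from fieldmark.classify import ClassifyTrainConfig
from fieldmark.embed import EmbedTrainConfig
from fieldmark.model import MarkerClassificationModel, PlotEmbeddingModel


def recovery_config(effect_size: float, seed: int = 0) -> fm.FieldConfig:
    """The standard recovery benchmark: 40 cultivars x 2 plots x 3 days x 4
    images at 64 px, one panicle-blob family, full per-image expression."""
    return fm.FieldConfig(
        n_cultivars=40,
        n_days=3,
        images_per_plot_day=4,
        image_size=(64, 64),
        families=(
            fm.FamilySpec(
                name="fam_panicle",
                trait=fm.TraitType.PANICLE_BLOB,
                effect_size=effect_size,
            ),
        ),
        expression_prob=1.0,
        seed=seed,
    )


def tiny_config(seed: int = 0, effect_size: float = 1.0) -> fm.FieldConfig:
    """A minutes-free campaign for fast contract tests."""
    return fm.FieldConfig(
        n_cultivars=8,
        n_days=1,
        images_per_plot_day=3,
        image_size=(32, 32),
        families=(
            fm.FamilySpec(
                name="fam_panicle",
                trait=fm.TraitType.PANICLE_BLOB,
                effect_size=effect_size,
            ),
        ),
        expression_prob=1.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def dataset_beta1() -> fm.SyntheticDataset:
    return fm.generate_arrays(recovery_config(1.0))


@pytest.fixture(scope="session")
def dataset_beta0() -> fm.SyntheticDataset:
    return fm.generate_arrays(recovery_config(0.0))


@pytest.fixture(scope="session")
def tiny_dataset() -> fm.SyntheticDataset:
    return fm.generate_arrays(tiny_config())


@pytest.fixture(scope="session")
def classifier_beta1(dataset_beta1):
    """Direct CNN classifier trained on the strong-effect campaign."""
    model = MarkerClassificationModel.from_dataset(dataset_beta1, seed=0)
    return model.fit(ClassifyTrainConfig(epochs=20, batch_size=100, seed=0))


@pytest.fixture(scope="session")
def classifier_beta0(dataset_beta0):
    """Identical pipeline on the zero-effect campaign (null control)."""
    model = MarkerClassificationModel.from_dataset(dataset_beta0, seed=0)
    return model.fit(ClassifyTrainConfig(epochs=20, batch_size=100, seed=0))


@pytest.fixture(scope="session")
def embedding_beta1(dataset_beta1):
    """Plot-identity embedding pre-trained on the strong-effect campaign
    (80 plots), with its marker split alongside."""
    split_model = MarkerClassificationModel.from_dataset(dataset_beta1, seed=0)
    em = PlotEmbeddingModel.from_dataset(dataset_beta1)
    results = em.fit(EmbedTrainConfig(seed=0))
    return results, split_model.split
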