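"""Shared fixtures: one synthetic study population per test session.

Heavy objects (rendered datasets, the trained grading model) are built once
at session scope; all tests draw from them with their own seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

import shiftwatch as sw
from shiftwatch import GeneratorSpec, TrainConfig

IMAGE_SIZE = 32


@pytest.fixture(scope="session")
def spec32() -> GeneratorSpec:
    return GeneratorSpec(image_size=IMAGE_SIZE)


@pytest.fixture(scope="session")
def dataset(spec32) -> sw.LabeledDataset:
    """In-distribution pool backing source/target samplers."""
    return sw.generate_dataset(spec32, 2000, fold="train", seed=101)


@pytest.fixture(scope="session")
def ood_dataset(spec32) -> sw.LabeledDataset:
    """Insufficient-quality pool, outside the source support."""
    return sw.generate_dataset(spec32, 400, fold="ood", seed=102)


@pytest.fixture(scope="session")
def test_pool(spec32) -> sw.LabeledDataset:
    """Held-out labelled fold for task-model evaluation and MUKS."""
    return sw.generate_dataset(spec32, 1500, fold="test", seed=103)


@pytest.fixture(scope="session")
def task_model(spec32):
    train = sw.generate_dataset(spec32, 1500, fold="train", seed=104)
    val = sw.generate_dataset(spec32, 300, fold="val", seed=105)
    return sw.train_task_classifier(train, val, TrainConfig(epochs=25, seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
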