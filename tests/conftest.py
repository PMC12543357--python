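"""Shared fixtures: synthetic datasets and small trained models.

Heavy artifacts (fixture directories, trained models) are session-scoped
so the suite trains as few models as possible.
"""

from __future__ import annotations

import pytest

from finmark.fixtures import FixtureParams, generate_dataset
from finmark.hpo import ParamRange, SearchRanges
from finmark.shape_model import Hyperparameters, train_predictor

#: Small-but-capable configuration for desk-scale fixture training.
TINY_HP = Hyperparameters(
    cascade_depth=4,
    tree_depth=2,
    trees_per_cascade=40,
    learning_rate=0.3,
    oversampling=4,
    feature_pool_size=120,
    test_splits=15,
    feature_pool_padding=0.05,
    regularization=0.1,
)

#: Mid-size configuration used where accuracy matters more than speed.
MEDIUM_HP = Hyperparameters(
    cascade_depth=8,
    tree_depth=3,
    trees_per_cascade=120,
    learning_rate=0.15,
    oversampling=10,
    feature_pool_size=300,
    test_splits=30,
    feature_pool_padding=0.05,
    regularization=0.1,
)

#: Desk-scale search ranges keeping a full cross-validated study fast.
TINY_RANGES = SearchRanges(
    cascade_depth=ParamRange(3, 5, integer=True),
    tree_depth=ParamRange(2, 3, integer=True),
    trees_per_cascade=ParamRange(30, 60, integer=True),
    learning_rate=ParamRange(0.1, 0.4, scale="log"),
    oversampling=ParamRange(3, 6, integer=True),
    feature_pool_size=ParamRange(80, 150, integer=True),
    test_splits=ParamRange(10, 20, integer=True),
    feature_pool_padding=ParamRange(0.0, 0.1),
    regularization=ParamRange(0.05, 0.2, scale="log"),
)


@pytest.fixture(scope="session")
def clean50(tmp_path_factory):
    """50 clean fixtures (seed 11) plus their ground-truth dataset."""
    out = tmp_path_factory.mktemp("clean50")
    out_dir, dataset = generate_dataset(50, FixtureParams(seed=11), out, overwrite=True)
    return out_dir, dataset


@pytest.fixture(scope="session")
def clean_small(tmp_path_factory):
    """12 clean fixtures (seed 23) for fast oracle tests."""
    out = tmp_path_factory.mktemp("clean12")
    out_dir, dataset = generate_dataset(12, FixtureParams(seed=23), out, overwrite=True)
    return out_dir, dataset


@pytest.fixture(scope="session")
def small_model(clean50):
    """One model trained on 30 of the clean fixtures with TINY_HP."""
    out_dir, dataset = clean50
    return train_predictor(dataset.subset(range(30)), TINY_HP, seed=5, image_root=out_dir)


@pytest.fixture
def tiny_hp():
    return TINY_HP


@pytest.fixture
def tiny_ranges():
    return TINY_RANGES
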