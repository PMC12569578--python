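import numpy as np
import pytest

from pathoftt import (
    FTTConfig,
    SimulationConfig,
    apply_preprocessor,
    binarize_column,
    fit_preprocessor,
    generate_annotation_table,
    stratified_split,
)
from pathoftt.ftt_core import init_model
from pathoftt.ssl_trainer import make_split_data


def build_ssl_problem(seed: int, n_variants: int = 3000, signal_strength: float = 2.0):
    """Simulate, split, preprocess: returns (train, val, test) SplitData plus
    the table, ground truth and test-row indices.

    Uses the compact study table (6 numerical / 2 categorical / 1 keyword
    columns) so a full pseudo-labeling run stays fast on one CPU.
    """
    config = SimulationConfig(
        n_variants=n_variants,
        n_numerical=6,
        n_categorical=2,
        n_keyword=1,
        cardinalities=(3, 4),
        signal_strength=signal_strength,
        seed=seed,
    )
    table, truth = generate_annotation_table(config)
    split = stratified_split(table.data["label"], seed=seed + 1)
    labels = binarize_column(table.data["label"])
    idx = {
        name: np.flatnonzero((split == name).to_numpy())
        for name in ("train", "validation", "test")
    }
    fitted = fit_preprocessor(table.subset_rows(idx["train"]))

    def split_data(i):
        design = apply_preprocessor(fitted, table.subset_rows(i))
        return make_split_data(design, labels.iloc[i].reset_index(drop=True), i)

    parts = tuple(split_data(idx[name]) for name in ("train", "validation", "test"))
    return parts, table, truth, idx, fitted


def compact_model_config(train_split, fitted) -> FTTConfig:
    """Scaled-down architecture used for CPU-sized training runs."""
    return FTTConfig(
        n_numerical=train_split.X_num.shape[1],
        categorical_cardinalities=tuple(fitted.categorical_cardinalities),
        token_dim=16,
        n_layers=2,
        n_heads=2,
        ffn_hidden=32,
    )


@pytest.fixture(scope="session")
def small_table():
    """One deterministic synthetic table shared by read-only tests."""
    config = SimulationConfig(
        n_variants=400,
        n_numerical=5,
        n_categorical=2,
        n_keyword=1,
        cardinalities=(3, 4),
        missing_rates=0.1,
        seed=42,
    )
    table, truth = generate_annotation_table(config)
    return config, table, truth


@pytest.fixture()
def tiny_model():
    """A small float64 model for exact numeric checks."""
    config = FTTConfig(
        n_numerical=3,
        categorical_cardinalities=(3, 4),
        token_dim=8,
        n_layers=2,
        n_heads=2,
        ffn_hidden=5,
        dropout_attention=0.0,
        dropout_ffn=0.0,
        dropout_residual=0.0,
    )
    return init_model(config, seed=3, dtype=np.float64)
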