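"""Shared fixtures: small property tables, datasets and fast model configs."""

import numpy as np
import pytest

from m6aconvkit.data_synth_io import (
    SynthConfig,
    generate_dataset,
    generate_dpp_table,
    labels_array,
)
from m6aconvkit.network import ArchitectureConfig
from m6aconvkit.sequence_features import encode_bundle, stack_bundles, znorm_dpp


@pytest.fixture(scope="session")
def dpp_table():
    """A 90-property synthetic table, Z-normalised."""
    return znorm_dpp(generate_dpp_table(90, seed=11))


@pytest.fixture(scope="session")
def nine_properties(dpp_table):
    return list(dpp_table.names[:9])


@pytest.fixture
def tiny_config():
    """Small architecture for fast unit-level training."""
    return ArchitectureConfig(
        conv_filters=(4, 6, 8),
        conv_kernels=(3, 3, 3),
        attention_hidden=32,
        learning_rate=3e-3,
        batch_size=32,
        epochs=4,
        seed=0,
    )


def make_xy(n_per_class, table, selected, seed=0, motif_rate_pos=1.0, **kwargs):
    """Planted-motif dataset encoded into batched branch arrays + labels."""
    cfg = SynthConfig(
        n_pos=n_per_class,
        n_neg=n_per_class,
        seed=seed,
        motif_rate_pos=motif_rate_pos,
        **kwargs,
    )
    data = generate_dataset(cfg)
    bundles = [encode_bundle(s, table, selected) for s in data]
    return data, stack_bundles(bundles), labels_array(data)


def split(X, y, n_test, seed=0):
    """Stratified train/test split of batched branch arrays."""
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    test = np.concatenate(
        [rng.choice(pos, n_test // 2, replace=False), rng.choice(neg, n_test // 2, replace=False)]
    )
    train = np.setdiff1d(np.arange(len(y)), test)
    take = lambda idx: {k: v[idx] for k, v in X.items()}  # noqa: E731
    return take(train), y[train], take(test), y[test]
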