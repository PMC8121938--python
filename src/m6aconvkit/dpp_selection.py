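"""Correlation-aware selection of dinucleotide physicochemical properties.

Four steps: (1) a logistic-regression classifier is cross-validated using
one property at a time, its per-sample feature being the property's
Z-normalised value at each of the L−1 overlapping dimer positions;
(2) properties are ranked by cross-validated MCC and the top 20 kept;
(3) Pearson correlation of each remaining property's 16-value dimer
vector with the topmost property's is computed; (4) properties with
|r| > 0.9 against the topmost are discarded as redundant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from m6aconvkit.data_synth_io import labels_array
from m6aconvkit.evaluation import confusion, metrics
from m6aconvkit.sequence_features import _DIMER_INDEX, DnaSequence, DppTable, znorm_dpp


@dataclass(frozen=True)
class PropertyScore:
    name: str
    mcc: float
    rank: int


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the four-step selection procedure."""

    ranked_top: tuple[PropertyScore, ...]
    selected: tuple[str, ...]
    #: Pearson r of every ranked property (except the topmost) with the topmost.
    correlations: dict[str, float]
    threshold: float

    @property
    def topmost(self) -> str:
        return self.ranked_top[0].name


def _dimer_index_matrix(sequences: Sequence[DnaSequence]) -> np.ndarray:
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
    (L,) = lengths
    if L < 2:
        raise ValueError("sequences must have length >= 2")
    return np.array(
        [[_DIMER_INDEX[s.bases[t : t + 2]] for t in range(L - 1)] for s in sequences],
        dtype=np.intp,
    )


def _cv_mcc(X: np.ndarray, y: np.ndarray, n_folds: int, seed: int) -> float:
    """Pooled out-of-fold MCC of a seeded, ridge-penalised logistic model."""
    if X.std() == 0.0:
        return 0.0
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.empty(len(y), dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        model = LogisticRegression(C=1.0, max_iter=1000, solver="lbfgs")
        model.fit(X[train_idx], y[train_idx])
        oof[test_idx] = model.predict(X[test_idx])
    return metrics(confusion(y, oof)).mcc


def score_property(
    sequences: Sequence[DnaSequence],
    table: DppTable,
    name: str,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated MCC of a logistic model driven by one property.

    The feature vector of a length-L sequence is the property's
    Z-normalised value at each of its L−1 dimer positions.
    """
    y = labels_array(sequences)
    if len(np.unique(y)) < 2:
        raise ValueError("property scoring requires both classes in the dataset")
    if table.znorm is None:
        table = znorm_dpp(table)
    row = table.znorm[table.index_of(name)]
    X = row[_dimer_index_matrix(sequences)]
    return _cv_mcc(X, y, n_folds, seed)


def rank_properties(
    sequences: Sequence[DnaSequence],
    table: DppTable,
    top_n: int = 20,
    n_folds: int = 5,
    seed: int = 0,
) -> list[PropertyScore]:
    """Score every property and return the ``top_n`` by MCC, descending.

    Ties are broken by table order (stable sort) for determinism.
    """
    y = labels_array(sequences)
    if len(np.unique(y)) < 2:
        raise ValueError("property ranking requires both classes in the dataset")
    if table.znorm is None:
        table = znorm_dpp(table)
    dimer_idx = _dimer_index_matrix(sequences)
    mccs = np.array(
        [_cv_mcc(table.znorm[j][dimer_idx], y, n_folds, seed) for j in range(len(table))]
    )
    if top_n > len(table):
        warnings.warn(f"top_n={top_n} exceeds the {len(table)} available properties; using all")
        top_n = len(table)
    order = np.argsort(-mccs, kind="stable")[:top_n]
    return [
        PropertyScore(name=table.names[j], mcc=float(mccs[j]), rank=r + 1)
        for r, j in enumerate(order)
    ]


def pearson_r(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation; r of a zero-variance vector is defined as 0 (warned)."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    su, sv = u.std(), v.std()
    if su == 0.0 or sv == 0.0:
        warnings.warn("zero-variance vector in Pearson correlation; treating r as 0")
        return 0.0
    return float(((u - u.mean()) * (v - v.mean())).mean() / (su * sv))


def prune_correlated(
    ranked: Sequence[PropertyScore],
    table: DppTable,
    threshold: float = 0.9,
) -> SelectionResult:
    """Drop ranked properties too correlated (|r| > threshold) with the topmost.

    Correlation uses the raw 16-value dimer vectors; Z-scoring leaves
    Pearson r unchanged, so this matches correlating the normalised
    vectors. Survivors keep their rank order; the topmost always stays.
    """
    if not ranked:
        raise ValueError("ranked property list is empty")
    top_vector = table.raw[table.index_of(ranked[0].name)]
    correlations: dict[str, float] = {}
    selected = [ranked[0].name]
    for score in ranked[1:]:
        r = pearson_r(table.raw[table.index_of(score.name)], top_vector)
        correlations[score.name] = r
        if -threshold <= r <= threshold:
            selected.append(score.name)
    return SelectionResult(
        ranked_top=tuple(ranked),
        selected=tuple(selected),
        correlations=correlations,
        threshold=threshold,
    )


def select_dpps(
    sequences: Sequence[DnaSequence],
    table: DppTable,
    top_n: int = 20,
    threshold: float = 0.9,
    n_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Run the full four-step selection procedure."""
    ranked = rank_properties(sequences, table, top_n=top_n, n_folds=n_folds, seed=seed)
    return prune_correlated(ranked, table, threshold=threshold)
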