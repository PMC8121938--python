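"""Binary-classification metrics, cross-validation and paired comparison.

Accuracy, sensitivity, specificity and Matthews correlation coefficient
follow the standard confusion-matrix formulas with the 6mA class as
positive; MCC with any zero factor in its denominator is defined as 0.
auROC is the rank statistic (ties credited one half). Cross-validation is
stratified and seeded, with jackknife (leave-one-out, pooled confusion) as
an alternative mode. Fold-wise scores of two methods are compared with a
one-tailed Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

ArrayLike = Sequence[int] | np.ndarray
#: fit_predict(X_train, y_train, X_test, fold_seed) -> scores for X_test
FitPredict = Callable[[object, np.ndarray, object, int], np.ndarray]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels: ArrayLike, predictions: ArrayLike) -> ConfusionCounts:
    """Count TP/FP/TN/FN with class 1 (6mA) as positive."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError(f"labels and predictions must be equal-length 1-D, got {y.shape} vs {p.shape}")
    for name, arr in (("labels", y), ("predictions", p)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Metric values for one evaluation (optionally one CV fold)."""

    acc: float
    sn: float
    sp: float
    mcc: float
    auroc: float | None = None
    fold: int | None = None
    counts: ConfusionCounts | None = None
    roc_points: np.ndarray | None = field(default=None, repr=False)  # (n, 2) of (fpr, tpr)

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "fold": self.fold,
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "mcc": self.mcc,
            "auroc": self.auroc,
        }


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Acc/Sn/Sp/MCC from confusion counts.

    Sn (Sp) is NaN-free: with an empty positive (negative) class the
    undefined rate is reported as 0. MCC's denominator is the root of
    the product of the four marginals; if any factor is zero, MCC = 0.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    acc = (tp + tn) / counts.total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(acc=acc, sn=sn, sp=sp, mcc=mcc, counts=counts)


def auroc(labels: ArrayLike, scores: Sequence[float] | np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Tied scores contribute one half, so a constant scorer earns exactly
    0.5. Both classes must be present.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D arrays")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auROC requires both classes to be present")
    ranks = stats.rankdata(s)  # average ranks handle ties = half credit
    rank_sum_pos = ranks[y == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(labels: ArrayLike, scores: Sequence[float] | np.ndarray) -> np.ndarray:
    """(fpr, tpr) pairs at every distinct score threshold, for plotting."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    n_pos = max(int((y == 1).sum()), 1)
    n_neg = max(int((y == 0).sum()), 1)
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # keep the last index of every tied-score block
    keep = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    return np.column_stack([fpr, tpr])


def evaluate_scores(labels: ArrayLike, scores: np.ndarray, fold: int | None = None) -> MetricsReport:
    """Full report (threshold 0.5, strict) from continuous scores."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    preds = (s > 0.5).astype(int)
    report = metrics(confusion(y, preds))
    return MetricsReport(
        acc=report.acc,
        sn=report.sn,
        sp=report.sp,
        mcc=report.mcc,
        auroc=auroc(y, s),
        fold=fold,
        counts=report.counts,
        roc_points=roc_points(y, s),
    )


@dataclass(frozen=True)
class CrossValidationResult:
    folds: tuple[MetricsReport, ...]
    mean: dict[str, float]
    pooled: MetricsReport
    seed: int
    mode: str


def _take(X: object, idx: np.ndarray) -> object:
    if isinstance(X, Mapping):
        return {k: np.asarray(v)[idx] for k, v in X.items()}
    return np.asarray(X)[idx]


def cross_validate(
    X: object,
    y: ArrayLike,
    fit_predict: FitPredict,
    k: int = 5,
    mode: str = "standard",
    seed: int = 0,
) -> CrossValidationResult:
    """Stratified k-fold (or jackknife) evaluation of a fit/score routine.

    ``X`` may be an array or a mapping of branch-name → array; rows are
    indexed jointly with ``y``. ``fit_predict`` trains from scratch on
    each training split and returns scores for the held-out split.

    Standard mode reports per-fold metrics and their mean plus a pooled
    report over the concatenated out-of-fold scores. Jackknife mode
    (leave-one-out) pools all n single-sample predictions into one
    confusion matrix, the conventional jackknife-testing report.
    """
    y = np.asarray(y)
    n = len(y)
    class_sizes = [int((y == c).sum()) for c in (0, 1)]
    if min(class_sizes) == 0:
        raise ValueError("cross-validation requires both classes")
    if mode == "jackknife":
        splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif mode == "standard":
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > min(class_sizes):
            raise ValueError(f"k={k} exceeds the smaller class size {min(class_sizes)}")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(n), y))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    oof_scores = np.empty(n, dtype=np.float64)
    fold_reports: list[MetricsReport] = []
    for fold_id, (train_idx, test_idx) in enumerate(splits):
        scores = np.asarray(
            fit_predict(_take(X, train_idx), y[train_idx], _take(X, test_idx), seed + fold_id)
        )
        oof_scores[test_idx] = scores
        if mode == "standard":
            fold_reports.append(evaluate_scores(y[test_idx], scores, fold=fold_id))

    pooled = evaluate_scores(y, oof_scores)
    if mode == "jackknife":
        return CrossValidationResult(
            folds=(), mean=dict(pooled.as_dict()), pooled=pooled, seed=seed, mode=mode
        )
    mean = {
        name: float(np.mean([getattr(r, name) for r in fold_reports]))
        for name in ("acc", "sn", "sp", "mcc", "auroc")
    }
    return CrossValidationResult(
        folds=tuple(fold_reports), mean=mean, pooled=pooled, seed=seed, mode=mode
    )


def undersample(y: ArrayLike, ratio: str | float = "1:1", seed: int = 0) -> np.ndarray:
    """Indices implementing random undersampling of positives to 1:r.

    All negatives are kept; positives are randomly subsampled (without
    replacement, seeded) so that positives:negatives = 1:r. If there are
    not enough positives to reach the ratio, all are kept with a
    warning. Returned indices are in ascending (original) order.
    """
    y = np.asarray(y)
    r = _parse_ratio(ratio)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    target = int(len(neg_idx) // r)
    if target >= len(pos_idx):
        if target > len(pos_idx):
            warnings.warn(
                f"not enough positives ({len(pos_idx)}) for 1:{r:g} ratio; keeping all"
            )
        keep_pos = pos_idx
    else:
        rng = np.random.default_rng(seed)
        keep_pos = rng.choice(pos_idx, size=target, replace=False)
    return np.sort(np.concatenate([keep_pos, neg_idx]))


def _parse_ratio(ratio: str | float) -> float:
    if isinstance(ratio, str):
        left, _, right = ratio.partition(":")
        if left.strip() != "1" or not right:
            raise ValueError(f"ratio must look like '1:r', got {ratio!r}")
        r = float(right)
    else:
        r = float(ratio)
    if r < 1:
        raise ValueError(f"ratio 1:{r:g} must have r >= 1")
    return r


def wilcoxon_one_tailed(
    scores_a: Sequence[float], scores_b: Sequence[float], alpha: float = 0.01
) -> tuple[float, bool]:
    """One-tailed Wilcoxon signed-rank test of "a > b" on paired scores.

    Zero differences are dropped (signed-rank convention); if all
    differences are zero the test is degenerate and reports p = 1 with
    no rejection. The exact null distribution is used for n ≤ 25 pairs,
    the continuity-corrected normal approximation above that.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score lists must be equal-length 1-D")
    diffs = a - b
    nonzero = int((diffs != 0).sum())
    if nonzero == 0:
        warnings.warn("all paired differences are zero; Wilcoxon test is degenerate")
        return 1.0, False
    method = "exact" if nonzero <= 25 else "approx"
    result = stats.wilcoxon(
        a, b, alternative="greater", zero_method="wilcox", correction=True, method=method
    )
    p = float(result.pvalue)
    return p, p < alpha
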