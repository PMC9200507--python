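"""Stratified k-fold cross-validation and binary classification metrics.

Metrics come from the four confusion counts:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F-score   = 2 TP / (2 TP + FP + FN)   (harmonic mean of P and R)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Zero-denominator cases return 0 with a warning. Latency is the wall-clock
model training time plus testing time; it is reported, never asserted, since
it depends on hardware.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import naive_bayes as nb
from .tabular import DataTable


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion_from_labels(
    y_true: np.ndarray, y_pred: np.ndarray, positive: int = 1
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} has a zero denominator; returning 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F-score, and MCC from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated rows")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    accuracy = (tp + tn) / c.total
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    f_score = _safe_ratio(2 * tp, 2 * tp + fp + fn, "F-score")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_ratio(tp * tn - fp * fn, mcc_den, "MCC")
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f_score": f_score,
        "mcc": mcc,
    }


def f_score_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def stratified_folds(
    labels: np.ndarray, k: int, seed: int = 0, stratified: bool = True
) -> list[np.ndarray]:
    """Partition row indices into k folds.

    Stratified (default): within each class, indices are shuffled and dealt
    round-robin, so per-class counts across folds differ by at most one.
    Non-stratified: a plain shuffled split. Deterministic given the seed.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratified:
        for cls in np.unique(labels):
            members = np.flatnonzero(labels == cls)
            if members.size < k:
                raise ValueError(
                    f"class {cls} has {members.size} rows, fewer than k={k} folds"
                )
            rng.shuffle(members)
            for i, idx in enumerate(members):
                folds[i % k].append(int(idx))
    else:
        if n < k:
            raise ValueError("fewer rows than folds")
        order = rng.permutation(n)
        for i, idx in enumerate(order):
            folds[i % k].append(int(idx))
    return [np.array(sorted(f), dtype=int) for f in folds]


@dataclass
class CVResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    pooled_confusion: ConfusionCounts
    train_time_s: float
    test_time_s: float
    metrics: dict[str, float] = field(default_factory=dict)
    per_fold_metrics: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.train_time_s < 0 or self.test_time_s < 0:
            raise ValueError("recorded times must be non-negative")


def latency(result: CVResult) -> float:
    """Training plus testing wall-clock time, in seconds."""
    if result.train_time_s < 0 or result.test_time_s < 0:
        raise ValueError("recorded times must be non-negative")
    return result.train_time_s + result.test_time_s


def cross_validate(
    table: DataTable,
    k: int = 10,
    seed: int = 0,
    nb_config: nb.NBConfig | None = None,
    stratified: bool = True,
    positive: int = 1,
    refit_normalizer: bool = False,
) -> CVResult:
    """k-fold CV of the Naive Bayes classifier on an imputed table.

    Each fold is held out once while the model is fitted on the remaining
    k-1 folds; fold accuracies are averaged and the held-out predictions are
    pooled into one confusion matrix for precision/recall/F/MCC.
    ``refit_normalizer`` refits min-max scaling on each training split and
    applies it to the held-out fold, for leakage-free evaluation; the default
    assumes the caller already normalized the full table once.
    """
    from .preprocess import apply_normalizer, fit_normalizer  # local: avoid cycle

    nb_config = nb_config or nb.NBConfig()
    folds = stratified_folds(table.labels, k, seed=seed, stratified=stratified)
    all_idx = np.arange(table.n_rows)
    fold_accuracies: list[float] = []
    per_fold_metrics: list[dict[str, float]] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    train_t = 0.0
    test_t = 0.0
    for held_out in folds:
        train_idx = np.setdiff1d(all_idx, held_out)
        train_table = table.take_rows(train_idx)
        test_table = table.take_rows(held_out)
        if refit_normalizer:
            params = fit_normalizer(train_table)
            train_table = apply_normalizer(train_table, params)
            test_table = apply_normalizer(test_table, params)
        t0 = time.perf_counter()
        model = nb.fit_nb(train_table, nb_config)
        t1 = time.perf_counter()
        preds = nb.predict(model, test_table)
        t2 = time.perf_counter()
        train_t += t1 - t0
        test_t += t2 - t1
        truth = table.labels[held_out]
        c = confusion_from_labels(truth, preds, positive=positive)
        pooled = pooled + c
        fold_accuracies.append(float(np.mean(preds == truth)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_fold_metrics.append(compute_metrics(c))
    return CVResult(
        fold_accuracies=fold_accuracies,
        mean_accuracy=float(np.mean(fold_accuracies)),
        pooled_confusion=pooled,
        train_time_s=train_t,
        test_time_s=test_t,
        metrics=compute_metrics(pooled),
        per_fold_metrics=per_fold_metrics,
    )
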