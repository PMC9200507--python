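"""Mixed Gaussian/categorical Naive Bayes for binary labels.

The posterior for class c given a row x is proportional to
``P(c) * prod_j P(x_j | c)`` — a Gaussian density for numeric features, a
Laplace-smoothed level frequency for categorical features. All likelihood
products are accumulated in log space and normalized at the end, so rows with
hundreds of features neither underflow nor overflow.

The module has two layers: array-level helpers (`fit_arrays`,
`log_joint`) that operate on pre-encoded numeric/categorical matrices and are
cheap enough to sit inside a wrapper feature-selection loop, and the
table-level API (:func:`fit_nb`, :func:`predict_proba`, :func:`predict`)
working on :class:`~mmaselect.tabular.DataTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tabular import CATEGORICAL, NUMERIC, DataTable, TableError

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class NBConfig:
    alpha: float = 1.0  # Laplace smoothing pseudo-count
    var_floor: float = 1e-9  # minimum per-(class, feature) variance

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.var_floor <= 0:
            raise ValueError("var_floor must be > 0")


@dataclass
class ArrayNB:
    """Fitted parameters over pre-encoded arrays (2 classes)."""

    log_priors: np.ndarray  # (2,)
    priors: np.ndarray  # (2,)
    means: np.ndarray  # (2, dn)
    variances: np.ndarray  # (2, dn), floored
    cat_log_probs: list[np.ndarray]  # per cat feature: (2, n_levels)
    class_counts: np.ndarray  # (2,)
    alpha: float


def encode_categoricals(
    frame: pd.DataFrame, levels: list[list[str]] | None = None
) -> tuple[np.ndarray, list[list[str]]]:
    """Integer-code categorical columns; unseen levels get code ``L`` (one
    past the training levels), which the smoothed likelihood still covers."""
    if levels is None:
        levels = [sorted(frame[c].dropna().unique()) for c in frame.columns]
    codes = np.empty((len(frame), frame.shape[1]), dtype=np.int64)
    for j, (col, levs) in enumerate(zip(frame.columns, levels)):
        lookup = {lev: i for i, lev in enumerate(levs)}
        codes[:, j] = [lookup.get(v, len(levs)) for v in frame[col]]
    return codes, levels


def fit_arrays(
    Xn: np.ndarray,
    Xc: np.ndarray,
    n_levels: np.ndarray,
    y: np.ndarray,
    config: NBConfig = NBConfig(),
) -> ArrayNB:
    """Fit priors, per-class Gaussian moments, and smoothed level tables.

    Xn: (n, dn) float matrix of numeric features (no NaN).
    Xc: (n, dc) int matrix of categorical codes in [0, n_levels[j]).
    n_levels: number of levels per categorical feature.
    """
    y = np.asarray(y)
    n = y.shape[0]
    counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
    if (counts == 0).any():
        raise TableError("each class needs at least one training row")
    priors = counts / n

    dn = Xn.shape[1]
    means = np.zeros((2, dn))
    variances = np.full((2, dn), config.var_floor)
    for c in (0, 1):
        rows = Xn[y == c]
        if dn:
            means[c] = rows.mean(axis=0)
            variances[c] = np.maximum(rows.var(axis=0), config.var_floor)

    cat_log_probs: list[np.ndarray] = []
    for j in range(Xc.shape[1]):
        L = int(n_levels[j])
        table = np.empty((2, L))
        for c in (0, 1):
            cnt = np.bincount(Xc[y == c, j], minlength=L)[:L].astype(float)
            table[c] = (cnt + config.alpha) / (counts[c] + config.alpha * L)
        cat_log_probs.append(np.log(table))
    return ArrayNB(
        log_priors=np.log(priors),
        priors=priors,
        means=means,
        variances=variances,
        cat_log_probs=cat_log_probs,
        class_counts=counts,
        alpha=config.alpha,
    )


def log_joint(model: ArrayNB, Xn: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    """(n, 2) matrix of log prior + log likelihood."""
    n = Xn.shape[0]
    lp = np.tile(model.log_priors, (n, 1))
    if model.means.shape[1]:
        for c in (0, 1):
            var = model.variances[c]
            diff = Xn - model.means[c]
            lp[:, c] += -0.5 * (LOG_2PI + np.log(var) + diff**2 / var).sum(axis=1)
    for j, table in enumerate(model.cat_log_probs):
        codes = Xc[:, j]
        L = table.shape[1]
        seen = codes < L
        for c in (0, 1):
            # unseen level: smoothed zero-count probability alpha / (n_c + alpha L)
            fallback = np.log(model.alpha) - np.log(
                model.class_counts[c] + model.alpha * L
            ) if model.alpha > 0 else -np.inf
            vals = np.where(seen, table[c, np.minimum(codes, L - 1)], fallback)
            lp[:, c] += vals
    return lp


def posterior_from_log_joint(lp: np.ndarray) -> np.ndarray:
    shifted = lp - lp.max(axis=1, keepdims=True)
    p = np.exp(shifted)
    return p / p.sum(axis=1, keepdims=True)


def labels_from_log_joint(lp: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Argmax with the tie rule: larger prior wins, then the lower index."""
    diff = lp[:, 1] - lp[:, 0]
    pred = (diff > 0).astype(np.int64)
    ties = diff == 0
    if ties.any():
        pred[ties] = 1 if priors[1] > priors[0] else 0
    return pred


@dataclass
class NBModel:
    """Table-level fitted model; remembers the column layout it was fit on."""

    core: ArrayNB
    numeric_columns: list[str]
    categorical_columns: list[str]
    cat_levels: list[list[str]]
    class_names: tuple[str, str]
    config: NBConfig = field(default_factory=NBConfig)

    @property
    def class_priors(self) -> np.ndarray:
        return self.core.priors


def split_encode(
    table: DataTable, model: NBModel | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a table into (numeric matrix, categorical codes, n_levels)."""
    num_cols = [
        n for n, k in zip(table.column_names, table.column_kinds) if k == NUMERIC
    ]
    cat_cols = [
        n for n, k in zip(table.column_names, table.column_kinds) if k == CATEGORICAL
    ]
    Xn = table.features[num_cols].to_numpy(dtype=float) if num_cols else np.empty(
        (table.n_rows, 0)
    )
    if np.isnan(Xn).any():
        raise TableError("numeric features contain missing values; impute first")
    if cat_cols:
        frame = table.features[cat_cols]
        if frame.isna().any().any():
            raise TableError("categorical features contain missing values; impute first")
        levels = model.cat_levels if model is not None else None
        Xc, levels = encode_categoricals(frame, levels)
        n_levels = np.array([len(l) for l in levels])
    else:
        Xc = np.empty((table.n_rows, 0), dtype=np.int64)
        levels = []
        n_levels = np.array([], dtype=np.int64)
    return Xn, Xc, n_levels


def fit_nb(table: DataTable, config: NBConfig = NBConfig()) -> NBModel:
    """Fit the mixed Naive Bayes model on an imputed table."""
    Xn, Xc, n_levels = split_encode(table)
    cat_cols = [
        n for n, k in zip(table.column_names, table.column_kinds) if k == CATEGORICAL
    ]
    levels = (
        [sorted(table.features[c].dropna().unique()) for c in cat_cols]
        if cat_cols
        else []
    )
    core = fit_arrays(Xn, Xc, n_levels, table.labels, config)
    num_cols = [
        n for n, k in zip(table.column_names, table.column_kinds) if k == NUMERIC
    ]
    return NBModel(core, num_cols, cat_cols, levels, table.class_names, config)


def _encode_like_model(table: DataTable, model: NBModel) -> tuple[np.ndarray, np.ndarray]:
    num = model.numeric_columns
    cat = model.categorical_columns
    missing = [c for c in num + cat if c not in table.column_names]
    if missing:
        raise TableError(f"table lacks columns the model was fit on: {missing}")
    Xn = table.features[num].to_numpy(dtype=float) if num else np.empty(
        (table.n_rows, 0)
    )
    if cat:
        Xc, _ = encode_categoricals(table.features[cat], model.cat_levels)
    else:
        Xc = np.empty((table.n_rows, 0), dtype=np.int64)
    return Xn, Xc


def predict_proba(model: NBModel, table: DataTable) -> np.ndarray:
    """(n, 2) posterior probabilities, normalized to sum to 1 per row."""
    Xn, Xc = _encode_like_model(table, model)
    return posterior_from_log_joint(log_joint(model.core, Xn, Xc))


def predict(model: NBModel, table: DataTable) -> np.ndarray:
    """Predicted 0/1 labels under the argmax-with-tie rule."""
    Xn, Xc = _encode_like_model(table, model)
    return labels_from_log_joint(log_joint(model.core, Xn, Xc), model.core.priors)
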