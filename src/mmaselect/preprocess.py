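"""Missing-value imputation, min-max normalization, and distance encodings.

Numeric missing cells are replaced by the column mean of the observed values;
categorical missing cells by the column mode. Min-max normalization maps each
numeric value p to (p - min_p) / (max_p - min_p) so training-range values land
in [0, 1]; a constant column maps to 0.0 (the ratio is undefined there and 0
keeps the range invariant).

Categorical columns are left as tokens by the normalizer. For
Euclidean-distance contexts (K-means), :func:`distance_matrix` one-hot
expands each categorical level into its own {0,1} coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tabular import NUMERIC, DataTable, TableError


@dataclass(frozen=True)
class NormalizationParams:
    """Observed per-numeric-column min/max, keyed by column name."""

    min_p: dict[str, float]
    max_p: dict[str, float]

    def __post_init__(self) -> None:
        for name in self.min_p:
            if self.min_p[name] > self.max_p[name]:
                raise TableError(f"min > max for column {name!r}")


def impute_missing(table: DataTable) -> DataTable:
    """Fill missing cells: numeric -> column mean, categorical -> column mode.

    Mode ties break to the lexicographically smallest level so imputation is
    deterministic. A fully-missing column is an error: there is nothing to
    impute from.
    """
    out = table.features.copy()
    for name, kind in zip(table.column_names, table.column_kinds):
        col = out[name]
        if not col.isna().any():
            continue
        observed = col.dropna()
        if observed.empty:
            raise TableError(f"column {name!r} is fully missing")
        if kind == NUMERIC:
            fill: object = float(observed.mean())
        else:
            counts = observed.value_counts()
            top = counts[counts == counts.max()].index
            fill = sorted(top)[0]
        out[name] = col.fillna(fill)
    return DataTable(out, table.column_kinds, table.labels.copy(), table.class_names)


def fit_normalizer(table: DataTable) -> NormalizationParams:
    """Record each numeric column's observed min and max."""
    if table.n_rows == 0:
        raise TableError("cannot fit a normalizer on an empty table")
    min_p: dict[str, float] = {}
    max_p: dict[str, float] = {}
    for name, kind in zip(table.column_names, table.column_kinds):
        if kind != NUMERIC:
            continue
        col = table.features[name].to_numpy(dtype=float)
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            raise TableError(f"column {name!r} has no observed values")
        min_p[name] = float(observed.min())
        max_p[name] = float(observed.max())
    return NormalizationParams(min_p, max_p)


def apply_normalizer(table: DataTable, params: NormalizationParams) -> DataTable:
    """Map every numeric cell p to (p - min_p) / (max_p - min_p)."""
    out = table.features.copy()
    for name, kind in zip(table.column_names, table.column_kinds):
        if kind != NUMERIC:
            continue
        if name not in params.min_p:
            raise TableError(f"normalizer has no parameters for column {name!r}")
        lo, hi = params.min_p[name], params.max_p[name]
        col = out[name].to_numpy(dtype=float)
        if hi == lo:
            scaled = np.where(np.isnan(col), np.nan, 0.0)
        else:
            scaled = (col - lo) / (hi - lo)
        out[name] = scaled
    return DataTable(out, table.column_kinds, table.labels.copy(), table.class_names)


def normalize(table: DataTable) -> DataTable:
    """Fit-and-apply min-max normalization on the same table."""
    return apply_normalizer(table, fit_normalizer(table))


def distance_matrix(table: DataTable) -> np.ndarray:
    """Real-vector encoding for Euclidean distance / K-means.

    Numeric columns pass through as floats; each categorical column expands
    to one {0,1} indicator per level (levels sorted for determinism). The
    table must be imputed first.
    """
    blocks: list[np.ndarray] = []
    for name, kind in zip(table.column_names, table.column_kinds):
        if kind == NUMERIC:
            col = table.features[name].to_numpy(dtype=float)
            if np.isnan(col).any():
                raise TableError(f"column {name!r} has missing values; impute first")
            blocks.append(col[:, None])
        else:
            col = table.features[name]
            if col.isna().any():
                raise TableError(f"column {name!r} has missing values; impute first")
            levels = sorted(col.unique())
            onehot = np.stack(
                [(col == lev).to_numpy(dtype=float) for lev in levels], axis=1
            )
            blocks.append(onehot)
    return np.hstack(blocks)
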