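"""Tabular dataset container and CSV/TSV/JSON input-output.

The canonical in-memory object is :class:`DataTable`: a feature matrix with
per-column type tags (numeric or categorical), a binary label vector, and the
two original label tokens. Every stage of the pipeline (imputation,
normalization, clustering, feature search, classification) consumes and
returns ``DataTable`` objects, so row and column accounting stays explicit.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

NUMERIC = "numeric"
CATEGORICAL = "categorical"

#: cell values treated as missing when reading files (UCI files use "?")
DEFAULT_MISSING_TOKENS = frozenset({"", "?", "NA"})


class TableError(ValueError):
    """Raised on malformed tables, schemas, or reports."""


@dataclass(frozen=True)
class ColumnSchema:
    """How to interpret a delimited text file.

    label_column: name or integer position of the class column; ``None``
        means the last column (the convention of the UCI-style files this
        toolkit targets).
    missing_tokens: strings mapped to a missing cell.
    delimiter: field separator; ``None`` infers from the file extension
        (``.tsv`` -> tab, otherwise comma).
    """

    label_column: str | int | None = None
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS
    delimiter: str | None = None


@dataclass
class DataTable:
    """Feature matrix + binary labels.

    features: DataFrame; numeric columns hold floats (NaN = missing),
        categorical columns hold strings (NaN = missing).
    column_kinds: tuple of ``"numeric"``/``"categorical"``, one per column.
    labels: int array of 0/1, one per row.
    class_names: the two original label tokens; ``class_names[i]`` is the
        token mapped to integer ``i``.
    """

    features: pd.DataFrame
    column_kinds: tuple[str, ...]
    labels: np.ndarray
    class_names: tuple[str, str]

    def __post_init__(self) -> None:
        self.features = self.features.reset_index(drop=True)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.column_kinds = tuple(self.column_kinds)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        names = list(self.features.columns)
        if len(set(names)) != len(names):
            raise TableError("duplicate column names")
        if len(self.column_kinds) != len(names):
            raise TableError("column_kinds length != number of columns")
        for kind in self.column_kinds:
            if kind not in (NUMERIC, CATEGORICAL):
                raise TableError(f"unknown column kind {kind!r}")
        if len(self.labels) != len(self.features):
            raise TableError("labels length != number of rows")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise TableError("labels must be binary 0/1")
        if len(self.class_names) != 2 or self.class_names[0] == self.class_names[1]:
            raise TableError("class_names must be two distinct tokens")
        for name, kind in zip(names, self.column_kinds):
            if kind == NUMERIC:
                col = self.features[name]
                if not pd.api.types.is_numeric_dtype(col):
                    raise TableError(f"numeric column {name!r} holds non-numbers")

    # -- conveniences ---------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def n_cols(self) -> int:
        return self.features.shape[1]

    @property
    def column_names(self) -> list[str]:
        return list(self.features.columns)

    def kind_of(self, name: str) -> str:
        return self.column_kinds[self.column_names.index(name)]

    def copy(self) -> "DataTable":
        return DataTable(
            self.features.copy(),
            self.column_kinds,
            self.labels.copy(),
            self.class_names,
        )

    def take_rows(self, indices: Sequence[int] | np.ndarray) -> "DataTable":
        idx = np.asarray(indices)
        return DataTable(
            self.features.iloc[idx].reset_index(drop=True),
            self.column_kinds,
            self.labels[idx],
            self.class_names,
        )

    def select_columns(self, mask: Sequence[bool]) -> "DataTable":
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.n_cols:
            raise TableError("mask length != number of columns")
        if not mask.any():
            raise TableError("cannot select zero columns")
        cols = [c for c, m in zip(self.column_names, mask) if m]
        kinds = tuple(k for k, m in zip(self.column_kinds, mask) if m)
        return DataTable(self.features[cols], kinds, self.labels, self.class_names)

    def __eq__(self, other: object) -> bool:  # value equality, for round-trips
        if not isinstance(other, DataTable):
            return NotImplemented
        if self.column_kinds != other.column_kinds:
            return False
        if self.class_names != other.class_names:
            return False
        if not np.array_equal(self.labels, other.labels):
            return False
        if list(self.features.columns) != list(other.features.columns):
            return False
        a, b = self.features, other.features
        if a.shape != b.shape:
            return False
        for name, kind in zip(self.column_names, self.column_kinds):
            if kind == NUMERIC:
                x = a[name].to_numpy(dtype=float)
                y = b[name].to_numpy(dtype=float)
                same = np.isclose(x, y, equal_nan=True)
                if not same.all():
                    return False
            else:
                x, y = a[name], b[name]
                if not ((x == y) | (x.isna() & y.isna())).all():
                    return False
        return True


def _infer_delimiter(path: str, schema: ColumnSchema) -> str:
    if schema.delimiter is not None:
        return schema.delimiter
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _parses_as_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_table(path: str, schema: ColumnSchema | None = None) -> DataTable:
    """Read a delimited text file with a header row into a :class:`DataTable`.

    Column kinds are inferred: a column is numeric iff every non-missing cell
    parses as a number. The label column (default: last) must carry exactly
    two distinct tokens; they are mapped to {0, 1} in lexicographic order.
    """
    schema = schema or ColumnSchema()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path,
        sep=_infer_delimiter(path, schema),
        dtype=str,
        keep_default_na=False,
        skipinitialspace=True,
    )
    if raw.shape[0] < 1:
        raise TableError("file has a header but no data rows")

    if schema.label_column is None:
        label_name = raw.columns[-1]
    elif isinstance(schema.label_column, int):
        label_name = raw.columns[schema.label_column]
    else:
        if schema.label_column not in raw.columns:
            raise TableError(f"label column {schema.label_column!r} not found")
        label_name = schema.label_column

    missing = schema.missing_tokens
    label_tokens = raw[label_name].astype(str).str.strip()
    if label_tokens.isin(missing).any():
        raise TableError("label column contains missing values")
    uniq = sorted(label_tokens.unique())
    if len(uniq) != 2:
        raise TableError(f"label column must have exactly 2 tokens, found {uniq}")
    class_names = (uniq[0], uniq[1])
    labels = (label_tokens == uniq[1]).to_numpy().astype(np.int64)

    feature_frame = raw.drop(columns=[label_name])
    if feature_frame.shape[1] == 0:
        raise TableError("no feature columns besides the label")

    cols: dict[str, pd.Series] = {}
    kinds: list[str] = []
    for name in feature_frame.columns:
        tokens = feature_frame[name].astype(str).str.strip()
        observed = tokens[~tokens.isin(missing)]
        numeric = len(observed) > 0 and observed.map(_parses_as_number).all()
        if numeric:
            vals = pd.to_numeric(tokens.where(~tokens.isin(missing)), errors="coerce")
            cols[name] = vals.astype(float)
            kinds.append(NUMERIC)
        else:
            cols[name] = tokens.where(~tokens.isin(missing))
            kinds.append(CATEGORICAL)
    return DataTable(pd.DataFrame(cols), tuple(kinds), labels, class_names)


def write_table(table: DataTable, path: str, delimiter: str | None = None) -> None:
    """Write a :class:`DataTable` back to delimited text (label column last)."""
    sep = delimiter or ("\t" if str(path).endswith((".tsv", ".tab")) else ",")
    out = table.features.copy()
    out["class"] = [table.class_names[y] for y in table.labels]
    out.to_csv(path, sep=sep, index=False, na_rep="?")


def _all_finite(obj) -> bool:
    if isinstance(obj, dict):
        return all(_all_finite(v) for v in obj.values())
    if isinstance(obj, (list, tuple)):
        return all(_all_finite(v) for v in obj)
    if isinstance(obj, bool):
        return True
    if isinstance(obj, (int, float, np.integer, np.floating)):
        return math.isfinite(float(obj))
    return True


def write_report(result: dict, path: str) -> None:
    """Serialize a result structure to JSON.

    Rejects non-finite metric values and empty selected-feature lists: a
    report that cannot be acted on should fail loudly at write time.
    """
    if not isinstance(result, dict):
        raise TableError("report must be a mapping")
    if not _all_finite(result):
        raise TableError("report contains non-finite values")
    if "selected_features" in result and len(result["selected_features"]) == 0:
        raise TableError("report has an empty selected-feature list")

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"unserializable object {o!r}")

    with open(path, "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_report(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
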