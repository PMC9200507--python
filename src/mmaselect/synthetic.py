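"""Synthetic clinical-style tables with planted, known ground truth.

The generator emulates the structure of small UCI-style chronic-disease
tables: a few hundred records, a binary class, a mix of numeric and
categorical attributes, some of which carry class signal, some of which are
redundant copies, some of which are pure noise, optionally with missing
cells and planted extreme-distance outlier rows.

Informative numeric features are Gaussian with class means separated by
``effect_size`` within-class standard deviations; for a balanced two-class
problem with m such independent features the Bayes-optimal accuracy is
Phi(effect_size * sqrt(m) / 2), which the generator reports so simulation
tests have a closed-form yardstick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .tabular import CATEGORICAL, NUMERIC, DataTable

#: redundant features are affine copies of an informative feature plus
#: N(0, REDUNDANT_NOISE_STD^2) jitter — detectable redundancy, not collinearity
REDUNDANT_NOISE_STD = 0.05

#: categorical informative features use this many levels, with per-class
#: level odds drawn from a Dirichlet perturbation of the uniform simplex
CATEGORICAL_LEVELS = 3
DIRICHLET_CONCENTRATION = 1.5


@dataclass(frozen=True)
class SyntheticSpec:
    n_rows: int = 768  # mirrors the size of a typical diabetes cohort table
    n_informative: int = 3
    n_redundant: int = 0
    n_noise: int = 5
    effect_size: float = 1.5  # class-mean separation in within-class SDs
    categorical_fraction: float = 0.0
    missing_rate: float = 0.0
    class_balance: float = 0.5  # P(class 1)
    outlier_rows: int = 0
    outlier_magnitude: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_informative + self.n_redundant + self.n_noise < 2:
            raise ValueError("need at least 2 features in total")
        for frac in (self.categorical_fraction, self.missing_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie strictly in (0, 1)")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant features need informative parents")
        if self.outlier_rows < 0:
            raise ValueError("outlier_rows must be >= 0")


@dataclass
class GroundTruth:
    informative: list[int]  # column indices carrying class signal
    redundant: list[int]
    noise: list[int]
    bayes_accuracy: float  # closed form, numeric-Gaussian part only
    outlier_rows: list[int] = field(default_factory=list)
    redundant_parent: dict[int, int] = field(default_factory=dict)


def _bayes_accuracy(delta: float, m_numeric: int, balance: float) -> float:
    """Optimal accuracy for m independent N(+-delta/2, 1) features.

    The log-likelihood ratio is Gaussian with mean +-Delta^2/2 and variance
    Delta^2, Delta = delta*sqrt(m); the prior log-odds shift the decision
    threshold when classes are unbalanced.
    """
    if m_numeric == 0 or delta == 0:
        return max(balance, 1 - balance)
    big_delta = delta * np.sqrt(m_numeric)
    b = np.log(balance / (1 - balance))
    acc1 = norm.cdf((big_delta**2 / 2 + b) / big_delta)
    acc0 = norm.cdf((big_delta**2 / 2 - b) / big_delta)
    return float(balance * acc1 + (1 - balance) * acc0)


def generate(spec: SyntheticSpec) -> tuple[DataTable, GroundTruth]:
    """Draw a table from the spec; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows
    labels = (rng.random(n) < spec.class_balance).astype(np.int64)
    signs = np.where(labels == 1, 1.0, -1.0)

    d = spec.n_informative + spec.n_redundant + spec.n_noise
    n_cat = int(round(spec.categorical_fraction * d))
    # distribute categorical slots over informative and noise features
    # (redundant copies stay numeric: they mirror a numeric parent)
    cat_informative = min(spec.n_informative, int(round(
        n_cat * spec.n_informative / max(spec.n_informative + spec.n_noise, 1)
    )))
    cat_noise = min(spec.n_noise, n_cat - cat_informative)

    columns: list[tuple[str, str, object]] = []  # (name, kind, values)
    informative_numeric_cols: list[np.ndarray] = []

    for i in range(spec.n_informative):
        name = f"inf_{i}"
        if i < spec.n_informative - cat_informative:
            vals = rng.normal(signs * spec.effect_size / 2.0, 1.0)
            informative_numeric_cols.append(vals)
            columns.append((name, NUMERIC, vals))
        else:
            base = np.full(CATEGORICAL_LEVELS, 1.0 / CATEGORICAL_LEVELS)
            probs0 = rng.dirichlet(base * DIRICHLET_CONCENTRATION * 10)
            shift = rng.dirichlet(base * DIRICHLET_CONCENTRATION)
            probs1 = 0.5 * probs0 + 0.5 * shift  # class-biased odds
            levels = np.array([f"lv{j}" for j in range(CATEGORICAL_LEVELS)])
            vals = np.where(
                labels == 0,
                rng.choice(levels, size=n, p=probs0),
                rng.choice(levels, size=n, p=probs1),
            )
            columns.append((name, CATEGORICAL, vals))

    for i in range(spec.n_redundant):
        parent_idx = int(rng.integers(len(informative_numeric_cols))) if (
            informative_numeric_cols
        ) else None
        if parent_idx is None:
            raise ValueError("redundant features need a numeric informative parent")
        parent = informative_numeric_cols[parent_idx]
        a = rng.uniform(0.5, 2.0) * (1 if rng.random() < 0.5 else -1)
        b = rng.uniform(-1.0, 1.0)
        vals = a * parent + b + rng.normal(0.0, REDUNDANT_NOISE_STD, size=n)
        columns.append((f"red_{i}", NUMERIC, vals))

    for i in range(spec.n_noise):
        name = f"noise_{i}"
        if i < cat_noise:
            levels = np.array([f"lv{j}" for j in range(CATEGORICAL_LEVELS)])
            probs = rng.dirichlet(
                np.full(CATEGORICAL_LEVELS, DIRICHLET_CONCENTRATION * 10)
            )
            vals = rng.choice(levels, size=n, p=probs)  # class-independent
            columns.append((name, CATEGORICAL, vals))
        else:
            columns.append((name, NUMERIC, rng.normal(0.0, 1.0, size=n)))

    order = rng.permutation(d)
    frame = pd.DataFrame(
        {columns[j][0]: columns[j][2] for j in order}
    )
    kinds = tuple(columns[j][1] for j in order)

    if spec.missing_rate > 0:
        blank = rng.random((n, d)) < spec.missing_rate
        for col_pos, name in enumerate(frame.columns):
            hit = blank[:, col_pos]
            if hit.all():  # never blank a full column
                hit[rng.integers(n)] = False
            if hit.any():
                col = frame[name].astype(object) if kinds[col_pos] == CATEGORICAL else frame[name]
                col = col.where(~hit)
                frame[name] = col

    table = DataTable(frame, kinds, labels, ("0", "1"))

    positions = {name: list(frame.columns).index(name) for name in frame.columns}
    truth = GroundTruth(
        informative=sorted(
            positions[f"inf_{i}"] for i in range(spec.n_informative)
        ),
        redundant=sorted(positions[f"red_{i}"] for i in range(spec.n_redundant)),
        noise=sorted(positions[f"noise_{i}"] for i in range(spec.n_noise)),
        bayes_accuracy=_bayes_accuracy(
            spec.effect_size,
            spec.n_informative - cat_informative,
            spec.class_balance,
        ),
    )

    if spec.outlier_rows > 0:
        table, planted = plant_outliers(
            table, spec.outlier_rows, spec.outlier_magnitude, seed=spec.seed + 1
        )
        truth.outlier_rows = list(planted)
    return table, truth


def plant_outliers(
    table: DataTable, count: int, magnitude: float, seed: int = 0
) -> tuple[DataTable, np.ndarray]:
    """Append ``count`` rows at ``magnitude`` x the data radius.

    The numeric coordinates of each planted row sit at the column-mean
    center plus ``magnitude * radius`` along a random direction, where the
    radius is the largest center-to-row distance in the clean data;
    categorical cells are sampled from the observed levels. Returns the new
    table and the indices of the planted rows (appended at the end).
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return table.copy(), np.array([], dtype=int)
    if magnitude <= 1:
        raise ValueError("magnitude must exceed 1 (outliers must be outside)")
    rng = np.random.default_rng(seed)

    num_cols = [
        n for n, k in zip(table.column_names, table.column_kinds) if k == NUMERIC
    ]
    if not num_cols:
        raise ValueError("planting outliers requires at least one numeric column")
    X = table.features[num_cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute the table before planting outliers")
    center = X.mean(axis=0)
    radius = float(np.sqrt(((X - center) ** 2).sum(axis=1)).max())
    if radius == 0:
        radius = 1.0

    rows = []
    for _ in range(count):
        direction = rng.normal(size=len(num_cols))
        direction /= np.linalg.norm(direction)
        coords = center + magnitude * radius * direction
        row: dict[str, object] = dict(zip(num_cols, coords))
        for name, kind in zip(table.column_names, table.column_kinds):
            if kind == CATEGORICAL:
                levels = table.features[name].dropna().unique()
                row[name] = rng.choice(levels)
        rows.append(row)
    extra = pd.DataFrame(rows)[table.column_names]
    features = pd.concat([table.features, extra], ignore_index=True)
    extra_labels = rng.integers(0, 2, size=count)
    labels = np.concatenate([table.labels, extra_labels])
    out = DataTable(features, table.column_kinds, labels, table.class_names)
    planted = np.arange(table.n_rows, table.n_rows + count)
    return out, planted


def compact_blobs(
    n_rows: int = 150,
    n_blobs: int = 2,
    n_features: int = 4,
    radius: float = 1.0,
    separation: float = 10.0,
    seed: int = 0,
) -> DataTable:
    """Bounded, well-separated clusters for outlier-filter fixtures.

    Rows are uniform inside balls of the given radius around centers spaced
    ``separation`` apart along the first axis. Uniform-in-ball clusters have
    bounded centroid distances (max distance < mean + 3 SD), so a z-score
    distance rule never flags a clean row — the property that makes exact
    planted-outlier recovery checkable. Labels alternate by blob parity.
    """
    rng = np.random.default_rng(seed)
    per = [n_rows // n_blobs + (1 if i < n_rows % n_blobs else 0) for i in range(n_blobs)]
    rows = []
    labels = []
    for b, m in enumerate(per):
        center = np.zeros(n_features)
        center[0] = b * separation
        # uniform in ball: normalized Gaussian direction x U^(1/d) radius
        direction = rng.normal(size=(m, n_features))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        r = radius * rng.random(m) ** (1.0 / n_features)
        rows.append(center + direction * r[:, None])
        labels.extend([b % 2] * m)
    X = np.vstack(rows)
    frame = pd.DataFrame({f"x{j}": X[:, j] for j in range(n_features)})
    return DataTable(
        frame, (NUMERIC,) * n_features, np.array(labels, dtype=np.int64), ("0", "1")
    )
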