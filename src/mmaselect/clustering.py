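"""Lloyd's K-means with Euclidean distance, used as an outlier filter.

The clusterer partitions records; :func:`remove_outliers` then drops records
whose distance to their assigned centroid is anomalous for that cluster
(mean + z_cut standard deviations of the member distances), plus any cluster
so small that its own distance statistics are meaningless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import distance_matrix
from .tabular import DataTable


@dataclass
class ClusterModel:
    centroids: np.ndarray  # (k, d)
    assignments: np.ndarray  # (n,)
    inertia: float
    k: int
    n_iterations: int
    inertia_history: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class OutlierRule:
    """Record-level outlier filter.

    z_cut: threshold in within-cluster standard deviations of the
        distance-to-centroid distribution. Default 3.
    max_drop_frac: hard cap on the fraction of rows the filter may drop,
        guarding against degenerate fits. Default 10%.
    min_cluster_frac: a cluster holding fewer than this fraction of rows
        (and fewer than 2 rows in any case) is treated as an outlier group
        and dropped whole — a lone centroid seated on an extreme point has
        distance 0 to itself and would otherwise shield it from the z rule.
    """

    z_cut: float = 3.0
    max_drop_frac: float = 0.10
    min_cluster_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.z_cut <= 0:
            raise ValueError("z_cut must be positive")
        if not 0 < self.max_drop_frac <= 1:
            raise ValueError("max_drop_frac must be in (0, 1]")
        if not 0 <= self.min_cluster_frac < 1:
            raise ValueError("min_cluster_frac must be in [0, 1)")


def euclidean_distance(a, b) -> float:
    """sqrt of the summed squared coordinate differences of two vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _assign(rows: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # squared distances; argmin breaks ties to the lowest cluster index
    d2 = ((rows[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _inertia(rows: np.ndarray, centroids: np.ndarray, assign: np.ndarray) -> float:
    diff = rows - centroids[assign]
    return float((diff**2).sum())


def fit_kmeans(
    rows: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    init: str = "forgy",
) -> ClusterModel:
    """Lloyd iterations until assignments stabilize or ``max_iter``.

    Initialization is Forgy by default (k distinct rows drawn uniformly by
    ``seed``); ``init="kmeans++"`` uses the distance-weighted seeding rule.
    An emptied cluster is reseeded at the row farthest from its current
    centroid. Deterministic given the seed.
    """
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    rng = np.random.default_rng(seed)

    if init == "forgy":
        centroids = rows[rng.choice(n, size=k, replace=False)].copy()
    elif init == "kmeans++":
        centroids = np.empty((k, rows.shape[1]))
        centroids[0] = rows[rng.integers(n)]
        closest = ((rows - centroids[0]) ** 2).sum(axis=1)
        for j in range(1, k):
            total = closest.sum()
            if total == 0:
                centroids[j] = rows[rng.integers(n)]
            else:
                centroids[j] = rows[rng.choice(n, p=closest / total)]
            closest = np.minimum(closest, ((rows - centroids[j]) ** 2).sum(axis=1))
    else:
        raise ValueError(f"unknown init {init!r}")

    assignments = _assign(rows, centroids)
    history = [_inertia(rows, centroids, assignments)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for j in range(k):  # recompute means; repair emptied clusters
            members = assignments == j
            if members.any():
                centroids[j] = rows[members].mean(axis=0)
            else:
                dist2 = ((rows - centroids[assignments]) ** 2).sum(axis=1)
                centroids[j] = rows[dist2.argmax()]
        new_assignments = _assign(rows, centroids)
        history.append(_inertia(rows, centroids, new_assignments))
        if history[-1] > history[-2] + 1e-9:
            raise AssertionError("inertia increased during Lloyd iteration")
        if np.array_equal(new_assignments, assignments):
            assignments = new_assignments
            break
        assignments = new_assignments
    return ClusterModel(
        centroids=centroids,
        assignments=assignments,
        inertia=history[-1],
        k=k,
        n_iterations=n_iter,
        inertia_history=history,
    )


def outlier_indices(
    rows: np.ndarray, model: ClusterModel, rule: OutlierRule
) -> np.ndarray:
    """Indices of rows flagged by the per-cluster distance rule."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    dist = np.sqrt(((rows - model.centroids[model.assignments]) ** 2).sum(axis=1))
    min_size = max(2, int(np.ceil(rule.min_cluster_frac * n)))
    flagged: list[int] = []
    for j in range(model.k):
        members = np.flatnonzero(model.assignments == j)
        if members.size == 0:
            continue
        if members.size < min_size:
            flagged.extend(members.tolist())
            continue
        d = dist[members]
        std = d.std()
        if std == 0:
            continue
        threshold = d.mean() + rule.z_cut * std
        flagged.extend(members[d > threshold].tolist())
    flagged_arr = np.array(sorted(flagged), dtype=int)
    cap = int(np.floor(rule.max_drop_frac * n))
    if flagged_arr.size > cap:
        warnings.warn(
            f"outlier filter flagged {flagged_arr.size} rows; capping at "
            f"{cap} ({rule.max_drop_frac:.0%} of {n})",
            stacklevel=2,
        )
        order = np.argsort(dist[flagged_arr])[::-1][:cap]
        flagged_arr = np.sort(flagged_arr[order])
    return flagged_arr


def remove_outliers(
    table: DataTable,
    model: ClusterModel,
    rule: OutlierRule | None = None,
    rows: np.ndarray | None = None,
) -> tuple[DataTable, np.ndarray]:
    """Drop outlying records; returns (filtered table, dropped row indices).

    ``rows`` is the real-vector encoding the model was fitted on; if omitted
    it is recomputed with :func:`mmaselect.preprocess.distance_matrix`.
    """
    rule = rule or OutlierRule()
    if rows is None:
        rows = distance_matrix(table)
    if rows.shape[0] != table.n_rows:
        raise ValueError("row encoding does not match the table")
    dropped = outlier_indices(rows, model, rule)
    keep = np.setdiff1d(np.arange(table.n_rows), dropped)
    return table.take_rows(keep), dropped


def column_outlier_indices(
    table: DataTable, model: ClusterModel, r_threshold: float = 0.1
) -> list[int]:
    """Literal "attribute" reading of the outlier step: feature columns whose
    encoded values barely correlate with the cluster split.

    Returns indices of columns whose maximum absolute point-biserial
    correlation (over the column's encoded coordinates) with the 2-cluster
    assignment is below ``r_threshold``. Provided for fidelity to the
    column-wise interpretation; rows mode is the default elsewhere.
    """
    if model.k != 2:
        raise ValueError("column mode requires k=2")
    member = (model.assignments == 1).astype(float)
    if member.std() == 0:
        return []
    flagged = []
    for idx, (name, kind) in enumerate(zip(table.column_names, table.column_kinds)):
        sub = table.select_columns(
            [i == idx for i in range(table.n_cols)]
        )
        enc = distance_matrix(sub)
        best = 0.0
        for col in enc.T:
            if col.std() == 0:
                continue
            r = abs(float(np.corrcoef(col, member)[0, 1]))
            best = max(best, r)
        if best < r_threshold:
            flagged.append(idx)
    return flagged
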