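"""Marker-set evaluation without ground-truth markers.

When no true marker list exists, a selected gene set is judged by how much
information it carries about the given clustering: (i) supervised — train a
classifier on the marker genes with the cluster labels as targets and score the
predictions (error = 1 - accuracy, class-size-weighted precision, Matthews
correlation coefficient); (ii) unsupervised — recluster the cells using only
the marker genes and compare to the original clustering (ARI, AMI, FMS). Both
run under 5-fold cross-validation: markers are selected and the classifier is
trained on four folds, the held-out fold is scored. Classification metrics are
computed once on the concatenated whole-dataset predictions; clustering metrics
are computed per fold and averaged (fold clusterings need not be compatible).

Method curves over a grid of marker-set sizes are summarized by an
average-of-medians (AoM) score per marker-range bin: for each metric in a
family take the median of the in-range points, then average across the family's
metrics; methods are then ranked (1 = best) per bin, classification and
clustering families separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata as _rankdata
from sklearn.metrics import (
    accuracy_score,
    adjusted_mutual_info_score,
    adjusted_rand_score,
    fowlkes_mallows_score,
    matthews_corrcoef,
    precision_score,
)
from sklearn.neighbors import kneighbors_graph

from .markers import ClusterLabels
from .ranking import CountMatrix, log_normalize

__all__ = [
    "FoldAssignment",
    "CentroidModel",
    "EvaluationReport",
    "make_folds",
    "train_ncc",
    "predict_ncc",
    "classification_metrics",
    "clustering_metrics",
    "louvain_grid_cluster",
    "cross_validated_evaluation",
    "aom_rank",
    "default_leiden_backend",
    "DEFAULT_RESOLUTIONS",
]

#: resolution grid r = 0.1, 0.2, ..., 3.0
DEFAULT_RESOLUTIONS: np.ndarray = np.round(np.arange(0.1, 3.0 + 1e-9, 0.1), 10)


@dataclass
class FoldAssignment:
    """Random partition of cells into K folds of near-equal size."""

    fold_of_cell: np.ndarray  # values in 1..K
    K: int
    seed: int

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_of_cell == fold


@dataclass
class CentroidModel:
    """Per-class mean profiles in log-normalized marker space."""

    centroids: np.ndarray  # (n_classes, n_markers)
    classes: np.ndarray
    markers: list[str]
    target_sum: float = 10_000.0
    log_base: float = 2.0


def make_folds(n: int, K: int = 5, seed: int = 0) -> FoldAssignment:
    """Uniform random K-fold partition; fold sizes differ by at most one."""
    if n < K:
        raise ValueError(f"cannot split {n} cells into {K} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of_cell = np.empty(n, dtype=int)
    base, extra = divmod(n, K)
    start = 0
    for f in range(1, K + 1):
        size = base + (1 if f <= extra else 0)
        fold_of_cell[perm[start : start + size]] = f
        start += size
    return FoldAssignment(fold_of_cell=fold_of_cell, K=K, seed=seed)


def train_ncc(
    X_train: CountMatrix, y_train: ClusterLabels | np.ndarray, markers: Sequence[str]
) -> CentroidModel:
    """Fit the nearest-centroids classifier on the marker genes.

    Training counts are log-normalized (library size 10,000, log2(1 + x)),
    restricted to the marker columns, and averaged within each class.
    """
    y = y_train.y if isinstance(y_train, ClusterLabels) else np.asarray(y_train)
    idx = X_train.gene_indexer(markers)  # raises on unknown markers
    L = log_normalize(X_train)
    L = L[:, idx]
    if sp.issparse(L):
        L = np.asarray(L.todense())
    classes = np.unique(y)
    centroids = np.vstack([L[y == k].mean(axis=0) for k in classes])
    return CentroidModel(centroids=centroids, classes=classes, markers=list(markers))


def predict_ncc(model: CentroidModel, X_test: CountMatrix) -> np.ndarray:
    """Assign each test cell the class of its nearest centroid (Euclidean).

    Test cells are log-normalized and restricted to the model's markers; ties
    go to the lowest class id.
    """
    idx = X_test.gene_indexer(model.markers)
    L = log_normalize(X_test, model.target_sum, model.log_base)
    L = L[:, idx]
    if sp.issparse(L):
        L = np.asarray(L.todense())
    # squared distances; argmin returns the first (lowest class id) on ties
    d2 = (L**2).sum(axis=1)[:, None] - 2 * L @ model.centroids.T
    d2 = d2 + (model.centroids**2).sum(axis=1)[None, :]
    return model.classes[np.argmin(d2, axis=1)]


def classification_metrics(y_true, y_pred) -> dict[str, float]:
    """Error (1 - accuracy), class-size-weighted precision, and multi-class MCC.

    Weighted precision averages the per-class precisions with weights equal to
    the true class sizes; classes never predicted contribute precision 0. MCC
    is the Gorodkin multi-class generalization from the full confusion matrix.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    return {
        "error": 1.0 - accuracy_score(y_true, y_pred),
        "weighted_precision": precision_score(
            y_true, y_pred, average="weighted", zero_division=0
        ),
        "mcc": matthews_corrcoef(y_true, y_pred),
    }


def clustering_metrics(labels_a, labels_b) -> dict[str, float]:
    """Chance-corrected partition agreement: ARI, AMI (arithmetic mean
    normalizer), and the Fowlkes-Mallows score.

    All three equal 1 for identical partitions (up to relabeling) and may be
    computed between partitions with different numbers of clusters.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.size == 0:
        raise ValueError("empty label vectors")
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return {
        "ari": adjusted_rand_score(labels_a, labels_b),
        "ami": adjusted_mutual_info_score(
            labels_a, labels_b, average_method="arithmetic"
        ),
        "fms": fowlkes_mallows_score(labels_a, labels_b),
    }


def default_leiden_backend(seed: int = 0) -> Callable:
    """A community-detection callable backed by igraph + leidenalg.

    Uses the resolution-parameterized modularity objective
    (RBConfigurationVertexPartition), the graph-clustering step the evaluation
    harness delegates. Returns ``f(adjacency_csr, resolution) -> labels``.
    """
    import igraph  # deferred: optional extra
    import leidenalg

    def cluster(adjacency: sp.spmatrix, resolution: float) -> np.ndarray:
        adj = sp.coo_matrix(adjacency)
        g = igraph.Graph(
            n=adj.shape[0], edges=list(zip(adj.row, adj.col)), directed=False
        )
        g.simplify()
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(resolution),
            seed=seed,
        )
        return np.asarray(part.membership)

    return cluster


def louvain_grid_cluster(
    X: CountMatrix,
    markers: Sequence[str],
    k_neighbors: int,
    ground_truth,
    cluster_fn: Callable | None = None,
    resolutions: Iterable[float] = DEFAULT_RESOLUTIONS,
) -> dict[str, float]:
    """Graph-cluster the marker space over a resolution grid; best score per metric.

    Cells are log-normalized and restricted to the markers; the k-NN graph is
    built on the marker space directly (the markers are already the retained
    dimensions, so no PCA). The injected ``cluster_fn(adjacency, resolution)``
    is run at every grid resolution and, for each of ARI / AMI / FMS
    *separately*, the maximum over the grid is reported (the optimal resolution
    may differ per metric).
    """
    ground_truth = np.asarray(
        ground_truth.y if isinstance(ground_truth, ClusterLabels) else ground_truth
    )
    if k_neighbors >= X.n_cells:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    if cluster_fn is None:
        cluster_fn = default_leiden_backend()
    idx = X.gene_indexer(markers)
    L = log_normalize(X)
    L = L[:, idx]
    if sp.issparse(L):
        L = np.asarray(L.todense())
    adj = kneighbors_graph(L, n_neighbors=k_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T)  # symmetrize to an undirected graph
    best = {"ari": -np.inf, "ami": -np.inf, "fms": -np.inf}
    for r in resolutions:
        labels = cluster_fn(adj, float(r))
        m = clustering_metrics(ground_truth, labels)
        for name, val in m.items():
            best[name] = max(best[name], val)
    return best


@dataclass
class EvaluationReport:
    """Tidy evaluation results.

    ``points``: long-format rows (method, fold, n_markers, n_markers_unique,
    metric, value); classification rows carry fold = 0 because they aggregate
    the full cross-validated prediction. ``aggregates``: per (method,
    n_markers, metric) means across folds, the table AoM ranking consumes.
    """

    points: pd.DataFrame
    aggregates: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False)


def cross_validated_evaluation(
    X: CountMatrix,
    y: ClusterLabels | np.ndarray,
    selector: Callable,
    marker_sizes: Sequence[int],
    K: int = 5,
    seed: int = 0,
    method: str = "selector",
    clustering: bool = False,
    cluster_fn: Callable | None = None,
    k_neighbors: int = 15,
    resolutions: Iterable[float] = DEFAULT_RESOLUTIONS,
) -> EvaluationReport:
    """Evaluate a marker selector under K-fold cross-validation.

    ``selector(train_counts, train_labels, size)`` must return marker gene ids
    selected using *only* the training folds; held-out cells never influence
    selection or training. For each requested size, classification metrics are
    computed once on the concatenated out-of-fold predictions; clustering
    metrics (optional) are computed on each held-out fold and averaged.
    """
    labels = y if isinstance(y, ClusterLabels) else ClusterLabels(np.asarray(y))
    folds = make_folds(X.n_cells, K=K, seed=seed)
    classes = labels.classes
    rows: list[dict] = []
    # predictions concatenated across folds, per marker-set size
    preds: dict[int, np.ndarray] = {
        m: np.empty(X.n_cells, dtype=classes.dtype) for m in marker_sizes
    }
    for f in range(1, K + 1):
        test = folds.test_mask(f)
        train = ~test
        y_tr = labels.y[train]
        missing = [k for k in classes if not np.any(y_tr == k)]
        if missing:
            raise ValueError(
                f"fold {f}: classes {missing} are absent from the training split"
            )
        X_tr = X.subset_cells(train)
        X_te = X.subset_cells(test)
        lab_tr = ClusterLabels(y_tr)
        for m in marker_sizes:
            markers = list(selector(X_tr, lab_tr, m))
            model = train_ncc(X_tr, lab_tr, markers)
            preds[m][np.flatnonzero(test)] = predict_ncc(model, X_te)
            rows.append(
                dict(
                    method=method,
                    fold=f,
                    n_markers=m,
                    n_markers_unique=len(set(markers)),
                    metric="n_markers_unique",
                    value=float(len(set(markers))),
                )
            )
            if clustering:
                cm = louvain_grid_cluster(
                    X_te,
                    markers,
                    k_neighbors=k_neighbors,
                    ground_truth=labels.y[test],
                    cluster_fn=cluster_fn,
                    resolutions=resolutions,
                )
                for name, val in cm.items():
                    rows.append(
                        dict(
                            method=method,
                            fold=f,
                            n_markers=m,
                            n_markers_unique=len(set(markers)),
                            metric=name,
                            value=float(val),
                        )
                    )
    for m in marker_sizes:
        for name, val in classification_metrics(labels.y, preds[m]).items():
            rows.append(
                dict(
                    method=method,
                    fold=0,
                    n_markers=m,
                    n_markers_unique=np.nan,
                    metric=name,
                    value=float(val),
                )
            )
    points = pd.DataFrame(rows)
    agg = (
        points[points.metric != "n_markers_unique"]
        .groupby(["method", "n_markers", "metric"], as_index=False)["value"]
        .mean()
    )
    return EvaluationReport(points=points, aggregates=agg)


#: metrics where smaller is better; converted to score form (1 - value) for AoM
ERROR_METRICS = frozenset({"error"})

DEFAULT_FAMILIES: Mapping[str, tuple[str, ...]] = {
    "classification": ("error", "weighted_precision", "mcc"),
    "clustering": ("ari", "ami", "fms"),
}


def aom_rank(
    aggregates: pd.DataFrame | EvaluationReport,
    marker_ranges: Sequence[tuple[float, float]],
    families: Mapping[str, Sequence[str]] = DEFAULT_FAMILIES,
    error_metrics: frozenset = ERROR_METRICS,
) -> pd.DataFrame:
    """Average-of-medians scores and 1-based ranks per marker-range bin.

    For each (method, range [a, b], family): take, for every metric in the
    family, the median of the metric over evaluated points with a <= n_markers
    <= b (no extrapolation — only evaluated points count; an empty range is an
    error naming the method and range), then average the medians. Error-type
    metrics are flipped to 1 - value first so larger is uniformly better. Ranks
    are assigned within each (range, family); 1 = largest AoM, ties share the
    minimum rank.
    """
    agg = aggregates.aggregates if isinstance(aggregates, EvaluationReport) else aggregates
    rows: list[dict] = []
    for lo, hi in marker_ranges:
        in_range = agg[(agg.n_markers >= lo) & (agg.n_markers <= hi)]
        for family, metrics in families.items():
            for m in sorted(agg.method.unique()):
                medians = []
                sub = in_range[in_range.method == m]
                for metric in metrics:
                    vals = sub[sub.metric == metric].value.to_numpy()
                    if vals.size == 0:
                        raise ValueError(
                            f"method {m!r} has no {metric!r} points in marker "
                            f"range [{lo}, {hi}]"
                        )
                    med = float(np.median(vals))
                    if metric in error_metrics:
                        med = 1.0 - med
                    medians.append(med)
                rows.append(
                    dict(
                        method=m,
                        range_lo=lo,
                        range_hi=hi,
                        family=family,
                        aom=float(np.mean(medians)),
                    )
                )
    out = pd.DataFrame(rows)
    out["rank"] = 0
    for (lo, hi, fam), grp in out.groupby(["range_lo", "range_hi", "family"]):
        out.loc[grp.index, "rank"] = _rankdata(-grp.aom.to_numpy(), method="min").astype(int)
    return out
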