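"""One-vs-all multi-class marker selection on ranked counts.

For each cluster k the binary selector correlates every gene's ranks with the
(ranked, centered) indicator of membership in k, and keeps the genes whose
correlation magnitude survives the sparsity budget s. Because the budget, not
a fixed list length, decides how many genes survive, clusters that are hard to
separate contribute more markers than clusters with a single clean marker. The
multi-class marker set is the deduplicated union of the per-cluster lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .ranking import (
    CountMatrix,
    center_ranked_indicator,
    rank_and_standardize,
    rank_vector,
)
from .solver import SelectSolution, correlation_vector, select_support

__all__ = [
    "ClusterLabels",
    "ClusterMarkers",
    "MarkerResult",
    "cluster_indicator",
    "rank_bin",
    "rank_corr",
    "spearman_scores",
    "prefer_gene",
    "equal_per_cluster_merge",
]


@dataclass
class ClusterLabels:
    """Integer cluster assignment for each cell."""

    y: np.ndarray
    codebook: dict[int, str] | None = None  # integer code -> original label

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 1:
            raise ValueError("labels must be a 1-D vector")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    @property
    def n_classes(self) -> int:
        return self.classes.size

    @classmethod
    def from_labels(cls, labels: Sequence) -> "ClusterLabels":
        """Map arbitrary (e.g. string) labels to stable integer codes."""
        labels = [str(v) for v in labels]
        uniq = sorted(set(labels))
        code = {v: i for i, v in enumerate(uniq)}
        y = np.array([code[v] for v in labels], dtype=int)
        return cls(y=y, codebook={i: v for v, i in code.items()})


@dataclass
class ClusterMarkers:
    """Ordered marker list for one cluster: genes by |coefficient| descending."""

    cluster: Any
    genes: list[str]
    coefficients: np.ndarray
    beta_star: float
    solution: SelectSolution | None = None

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class MarkerResult:
    """Per-cluster marker lists plus their deduplicated union."""

    per_cluster: dict[Any, ClusterMarkers]
    union: list[str]
    s: float
    n_markers_per_cluster: dict[Any, int] = field(default_factory=dict)


def cluster_indicator(y: ClusterLabels | np.ndarray, k) -> np.ndarray:
    """The +/-1 membership vector of class k: +1 where y == k, else -1."""
    yv = y.y if isinstance(y, ClusterLabels) else np.asarray(y)
    if not np.any(yv == k):
        raise ValueError(f"class {k!r} is not present in the labels")
    return np.where(yv == k, 1.0, -1.0)


def _order_support(solution: SelectSolution) -> np.ndarray:
    """Support indices by |coefficient| descending, ties by index."""
    sup = solution.support
    mag = np.abs(solution.omega_hat[sup])
    order = np.lexsort((sup, -mag))
    return sup[order]


def rank_bin(X: CountMatrix, tau, s: float, _Xbar=None) -> ClusterMarkers:
    """Binary marker selection: one group (tau = +1) against the rest.

    Ranks and standardizes the counts, ranks and centers the indicator, forms
    the correlation vector, and solves the sparse maximization. The support is
    mapped back to original gene ids (constant genes can never appear).
    """
    Xbar = rank_and_standardize(X) if _Xbar is None else _Xbar
    tau_bar = center_ranked_indicator(tau)
    v = correlation_vector(Xbar, tau_bar)
    sol = select_support(v, s)
    ordered = _order_support(sol)
    genes = [Xbar.gene_ids[j] for j in ordered]
    return ClusterMarkers(
        cluster=None,
        genes=genes,
        coefficients=sol.omega_hat[ordered],
        beta_star=sol.beta_star,
        solution=sol,
    )


def rank_corr(X: CountMatrix, y: ClusterLabels | np.ndarray, s: float) -> MarkerResult:
    """Multi-class marker selection: the binary selector once per cluster.

    The ranked, standardized matrix is computed a single time and shared across
    clusters; only the indicator changes. The sparsity budget s is the same for
    every cluster, so different clusters select different (informative) numbers
    of markers. The union preserves class order (ascending class code) and,
    within a class, the |coefficient|-descending marker order.
    """
    labels = y if isinstance(y, ClusterLabels) else ClusterLabels(np.asarray(y))
    if labels.n_classes < 2:
        raise ValueError("multi-class selection needs at least 2 classes")
    Xbar = rank_and_standardize(X)
    per_cluster: dict[Any, ClusterMarkers] = {}
    union: list[str] = []
    seen: set[str] = set()
    for k in labels.classes:
        tau = cluster_indicator(labels, k)
        cm = rank_bin(X, tau, s, _Xbar=Xbar)
        cm.cluster = k
        per_cluster[k] = cm
        for g in cm.genes:
            if g not in seen:
                seen.add(g)
                union.append(g)
    return MarkerResult(
        per_cluster=per_cluster,
        union=union,
        s=float(s),
        n_markers_per_cluster={k: len(cm) for k, cm in per_cluster.items()},
    )


def spearman_scores(
    X: CountMatrix, y: ClusterLabels | np.ndarray
) -> dict[Any, np.ndarray]:
    """Per class, |Spearman correlation| of every gene with the class indicator.

    Scores align with the original gene columns; constant genes score 0. Within
    a class, the selector's marker ordering agrees with descending score order,
    which is what makes the method interpretable as a correlation ranking.
    """
    labels = y if isinstance(y, ClusterLabels) else ClusterLabels(np.asarray(y))
    if labels.n_classes < 2:
        raise ValueError("need at least 2 classes")
    Xbar = rank_and_standardize(X)
    n = X.n_cells
    out: dict[Any, np.ndarray] = {}
    for k in labels.classes:
        tau = cluster_indicator(labels, k)
        tau_bar = center_ranked_indicator(tau)
        sigma_tau = rank_vector(tau).std()
        v = correlation_vector(Xbar, tau_bar)
        scores = np.zeros(X.n_genes)
        scores[Xbar.kept_genes] = np.abs(v) / (n * sigma_tau)
        out[k] = scores
    return out


def prefer_gene(X: CountMatrix, tau, j: int, k: int) -> int:
    """Of two genes, the one selected more favorably for the group tau.

    Returns the gene with the larger |Spearman correlation| with tau; ties go
    to the lower gene index. Both genes must be non-constant.
    """
    for g in (j, k):
        col = X.column(g)
        if col.max() == col.min():
            raise ValueError(f"gene {g} is constant across cells")
    tau_bar = center_ranked_indicator(tau)
    n = X.n_cells

    def score(g: int) -> float:
        r = rank_vector(X.column(g))
        rs = (r - r.mean()) / r.std()
        return abs(float(tau_bar @ rs)) / (n * rank_vector(tau).std())

    sj, sk = score(j), score(k)
    if sj > sk:
        return j
    if sk > sj:
        return k
    return min(j, k)


def equal_per_cluster_merge(
    scores: Mapping[Any, np.ndarray],
    m: int,
    gene_ids: Sequence[str] | None = None,
) -> list:
    """Top-m genes per class by score, unioned with duplicates removed.

    This is the merging rule used for score-list comparator methods: every
    class contributes the same number of genes (ties broken toward the lower
    gene index). NaN scores mark unscored genes; a class with fewer than m
    scored genes contributes all of them. Returns gene ids if provided, else
    column indices, in first-seen order (class order, then rank within class).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    union: list = []
    seen: set = set()
    for k in sorted(scores.keys()):
        sc = np.asarray(scores[k], dtype=float)
        valid = np.flatnonzero(~np.isnan(sc))
        order = valid[np.lexsort((valid, -sc[valid]))]
        for j in order[:m]:
            key = gene_ids[j] if gene_ids is not None else int(j)
            if key not in seen:
                seen.add(key)
                union.append(key)
    return union
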