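"""Rank transformation of count vectors and the normalizations built on it.

scRNA-seq UMI counts are sparse, integer valued and heavy tailed. Replacing each
gene's counts by their tie-averaged ranks is a non-parametric normalization: it
compresses the gap between the largest counts while expanding the gap between
"no expression" (the large tie group at zero) and "some expression". Marker
selection downstream operates entirely on these ranks, so the raw counts never
need library-size normalization first. Library-size + log normalization is still
provided here because the marker-set *evaluation* protocol (classification and
clustering on the selected genes) works in conventional log-normalized space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

__all__ = [
    "CountMatrix",
    "RankedMatrix",
    "rank_vector",
    "rank_and_standardize",
    "center_ranked_indicator",
    "log_normalize",
]


@dataclass
class CountMatrix:
    """A cells x genes matrix of nonnegative counts with gene identifiers.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` dense ndarray or scipy sparse matrix. Entries must
        be nonnegative and finite; UMI data are integer valued but integrality is
        not enforced so that externally normalized matrices can be carried too.
    gene_ids
        One string per gene column.
    cell_ids
        One string per cell row; generated as ``cell_0 .. cell_{n-1}`` if omitted.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
            data = self.values.data
        else:
            self.values = np.asarray(self.values)
            if self.values.ndim != 2:
                raise ValueError("counts must be a 2-D cells x genes matrix")
            data = self.values
        if data.size and (not np.all(np.isfinite(data))):
            raise ValueError("counts contain non-finite or missing values")
        if data.size and data.min() < 0:
            raise ValueError("counts must be nonnegative")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 cells")
        if p < 1:
            raise ValueError("need at least 1 gene")
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.gene_ids) != p:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {p} gene columns"
            )
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene ids must be unique")
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        elif len(self.cell_ids) != n:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n} cell rows"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def column(self, j: int) -> np.ndarray:
        """Dense 1-D counts of gene column ``j``."""
        if sp.issparse(self.values):
            return np.asarray(self.values[:, j].todense(), dtype=float).ravel()
        return np.asarray(self.values[:, j], dtype=float)

    def gene_indexer(self, gene_ids) -> np.ndarray:
        """Column indices of ``gene_ids``, in order; unknown ids raise."""
        lookup = {g: j for j, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[str(g)] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown gene id {exc.args[0]!r}") from None

    def subset_genes(self, gene_ids) -> "CountMatrix":
        idx = self.gene_indexer(gene_ids)
        return CountMatrix(
            self.values[:, idx], [self.gene_ids[j] for j in idx], list(self.cell_ids)
        )

    def subset_cells(self, rows) -> "CountMatrix":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return CountMatrix(
            self.values[rows, :], list(self.gene_ids), [self.cell_ids[i] for i in rows]
        )


@dataclass
class RankedMatrix:
    """Column-standardized matrix with the bookkeeping of dropped constant genes.

    ``values`` holds one column per *kept* gene, each with mean 0 and population
    standard deviation 1. ``kept_genes`` / ``dropped_genes`` are column indices
    into the original matrix; a constant gene has zero rank variance and can
    never discriminate groups, so it is removed before selection.
    """

    values: np.ndarray
    kept_genes: np.ndarray
    dropped_genes: np.ndarray
    gene_ids: list[str] = field(default_factory=list)


def rank_vector(x) -> np.ndarray:
    """Tie-averaged ranks of ``x``: rank_i = #{x_l < x_i} + (#{x_l = x_i} + 1)/2.

    Tied values share the average of the ranks they span, so the ranks of
    ``(17, 17, 4, 308, 17)`` are ``(3, 3, 1, 5, 3)``. Sum of ranks is always
    ``n(n+1)/2`` and any strictly increasing transform of ``x`` leaves the
    ranks unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot rank an empty vector")
    return rankdata(x, method="average")


def rank_and_standardize(X: CountMatrix) -> RankedMatrix:
    """Rank each gene column, then center and scale to unit population sd.

    Column j of the result is ``(ranks_j - mean(ranks_j)) / sd(ranks_j)`` with
    the population standard deviation (divide by n). Genes constant across all
    cells (zero rank variance) are dropped and recorded.
    """
    A = X.dense()
    ranks = rankdata(A, method="average", axis=0)
    sd = ranks.std(axis=0)  # ddof=0: population sd
    kept = np.flatnonzero(sd > 0)
    dropped = np.flatnonzero(sd == 0)
    if kept.size == 0:
        raise ValueError("no informative genes: all gene columns are constant")
    vals = (ranks[:, kept] - ranks[:, kept].mean(axis=0)) / sd[kept]
    return RankedMatrix(
        values=vals,
        kept_genes=kept,
        dropped_genes=dropped,
        gene_ids=[X.gene_ids[j] for j in kept],
    )


def center_ranked_indicator(tau) -> np.ndarray:
    """Ranked and centered class indicator: ``rank(tau) - mean(rank(tau))``.

    ``tau`` must be a +/-1 vector with both signs present. The result sums to
    zero, takes exactly two values, and is positive exactly where tau = +1;
    replacing tau by this vector leaves the selected markers unchanged but
    makes the gene scores exact (unnormalized) Spearman correlations.
    """
    tau = np.asarray(tau, dtype=float)
    vals = set(np.unique(tau))
    if not vals <= {-1.0, 1.0}:
        raise ValueError("tau must contain only +1 and -1")
    if vals != {-1.0, 1.0}:
        raise ValueError("tau must contain at least one cell of each class")
    r = rank_vector(tau)
    return r - r.mean()


def log_normalize(X: CountMatrix, target_sum: float = 10_000.0, log_base: float = 2.0):
    """Library-size normalize each cell to ``target_sum`` then take log(1 + x).

    Each row is rescaled so its total is ``target_sum`` (all-zero cells are
    passed through unchanged — filtering cells is the caller's responsibility),
    then every entry e becomes ``log_base``-logarithm of (1 + e). Zero entries
    stay zero. Sparse input yields sparse output.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    V = X.values
    if sp.issparse(V):
        V = V.tocsr().astype(float)
        totals = np.asarray(V.sum(axis=1)).ravel()
        scale = np.divide(target_sum, totals, out=np.ones_like(totals), where=totals > 0)
        out = sp.diags(scale) @ V
        out = out.log1p()
        out.data /= np.log(log_base)
        return out.tocsr()
    V = np.asarray(V, dtype=float)
    if V.size and V.min() < 0:
        raise ValueError("counts must be nonnegative")
    totals = V.sum(axis=1)
    scale = np.divide(target_sum, totals, out=np.ones_like(totals), where=totals > 0)
    return np.log1p(V * scale[:, None]) / np.log(log_base)
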