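"""Reading and writing counts, labels, and marker tables.

On disk, counts are either a MatrixMarket coordinate file with companion
``genes.tsv`` / ``barcodes.tsv`` files (the 10x layout, genes x cells, which is
transposed on load) or a dense CSV/TSV with cell rows and gene columns. In
memory the orientation is always cells x genes. Gene identity is carried by
string id, never by position, across every filtering step.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .markers import ClusterLabels, ClusterMarkers, MarkerResult
from .ranking import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_labels",
    "write_markers",
    "read_markers",
]


def read_counts(
    path,
    fmt: str | None = None,
    genes_path=None,
    cells_path=None,
    orientation: str = "genes-by-cells",
) -> CountMatrix:
    """Load a count matrix from MTX (10x triple) or dense CSV/TSV.

    ``fmt`` is inferred from the suffix when omitted. For MTX, companion gene
    and barcode files default to ``genes.tsv`` / ``barcodes.tsv`` next to the
    matrix; ``orientation`` says how the file is laid out on disk
    ("genes-by-cells", the 10x convention and the default, or
    "cells-by-genes"). CSV/TSV files are cells x genes with a header row of
    gene ids and a first column of cell ids.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if orientation not in ("genes-by-cells", "cells-by-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if fmt == "mtx":
        M = scipy.io.mmread(str(path))
        if sp.issparse(M):
            M = M.tocsr()
        else:
            M = np.asarray(M)
        if orientation == "genes-by-cells":
            M = M.T.tocsr() if sp.issparse(M) else M.T
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        cells_path = Path(cells_path) if cells_path else path.parent / "barcodes.tsv"
        gene_ids = _read_id_column(genes_path)
        cell_ids = _read_id_column(cells_path)
        if len(gene_ids) != M.shape[1]:
            raise ValueError(
                f"{len(gene_ids)} gene ids in {genes_path.name} but the matrix "
                f"has {M.shape[1]} genes"
            )
        if len(cell_ids) != M.shape[0]:
            raise ValueError(
                f"{len(cell_ids)} barcodes in {cells_path.name} but the matrix "
                f"has {M.shape[0]} cells"
            )
        return CountMatrix(values=M, gene_ids=gene_ids, cell_ids=cell_ids)
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric entries in {path.name}")
    return CountMatrix(
        values=values,
        gene_ids=[str(g) for g in df.columns],
        cell_ids=[str(c) for c in df.index],
    )


def _read_id_column(path: Path) -> list[str]:
    # 10x genes.tsv may carry two columns (ensembl id, symbol); use the first.
    ids = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            ids.append(line.split("\t")[0].split(",")[0].strip())
    return ids


def write_counts(X: CountMatrix, out_dir) -> dict[str, Path]:
    """Write counts as matrix.mtx (genes x cells) + genes.tsv + barcodes.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    V = X.values if sp.issparse(X.values) else sp.csr_matrix(X.values)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), V.T.tocoo(), field="integer")
    paths["genes"].write_text("".join(g + "\n" for g in X.gene_ids))
    paths["barcodes"].write_text("".join(c + "\n" for c in X.cell_ids))
    return paths


def read_labels(path, counts: CountMatrix | None = None) -> ClusterLabels:
    """Read one cluster label per cell (single-column text/CSV, matrix order).

    String labels are mapped to stable integer codes (sorted label order) with
    the codebook kept on the result. If ``counts`` is given the length must
    match its number of cells.
    """
    raw = [
        line.strip().split(",")[0].split("\t")[0]
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
    if raw and raw[0].lower() in ("label", "cluster", "labels"):
        raw = raw[1:]
    if counts is not None and len(raw) != counts.n_cells:
        raise ValueError(
            f"{len(raw)} labels in {Path(path).name} but the counts matrix has "
            f"{counts.n_cells} cells"
        )
    return ClusterLabels.from_labels(raw)


def write_markers(result: MarkerResult, out_dir, seed: int | None = None) -> dict:
    """Write per-cluster marker TSVs, the union TSV and a JSON manifest.

    ``markers_cluster_<k>.tsv`` columns: cluster, gene, coefficient, rank
    (1 = strongest within the cluster); ``markers_union.tsv`` one gene per
    line in the deduplicated union order. Deterministic byte-for-byte given
    the same result.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for k in sorted(result.per_cluster.keys()):
        cm = result.per_cluster[k]
        df = pd.DataFrame(
            {
                "cluster": [k] * len(cm.genes),
                "gene": cm.genes,
                "coefficient": np.asarray(cm.coefficients, dtype=float),
                "rank": np.arange(1, len(cm.genes) + 1),
            }
        )
        p = out_dir / f"markers_cluster_{k}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written[f"cluster_{k}"] = p
    union_path = out_dir / "markers_union.tsv"
    union_path.write_text("".join(g + "\n" for g in result.union))
    written["union"] = union_path
    manifest = {
        "s": result.s,
        "seed": seed,
        "version": __version__,
        "n_markers_per_cluster": {
            str(k): int(v) for k, v in result.n_markers_per_cluster.items()
        },
        "n_markers_union": len(result.union),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = manifest_path
    return written


def read_markers(out_dir) -> MarkerResult:
    """Re-assemble a MarkerResult written by :func:`write_markers`."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    per_cluster: dict = {}
    for p in sorted(out_dir.glob("markers_cluster_*.tsv")):
        df = pd.read_csv(p, sep="\t", dtype={"gene": str})
        k = df.cluster.iloc[0] if len(df) else p.stem.removeprefix("markers_cluster_")
        per_cluster[k] = ClusterMarkers(
            cluster=k,
            genes=[str(g) for g in df.gene],
            coefficients=df.coefficient.to_numpy(),
            beta_star=np.nan,
        )
    union = [
        g for g in (out_dir / "markers_union.tsv").read_text().splitlines() if g
    ]
    return MarkerResult(
        per_cluster=per_cluster,
        union=union,
        s=float(manifest["s"]),
        n_markers_per_cluster={k: len(cm) for k, cm in per_cluster.items()},
    )
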