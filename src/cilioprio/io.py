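"""Reading and writing of the on-disk formats used across the pipeline.

Count matrices travel as MatrixMarket (.mtx, genes x cells as 10x-style
exports) with ``genes.tsv`` / ``barcodes.tsv`` sidecars; everything tabular is
plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_marker_reference",
    "write_marker_reference",
]


def read_count_matrix(directory) -> ad.AnnData:
    """Load an MTX directory (matrix.mtx, genes.tsv, barcodes.tsv) as AnnData.

    The matrix on disk is genes x cells; the returned AnnData is cells x genes
    (obs = cells, var = genes), the in-memory convention of the ecosystem.
    """
    d = Path(directory)
    mat = spio.mmread(d / "matrix.mtx").tocsr().T
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return adata


def write_count_matrix(adata: ad.AnnData, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    spio.mmwrite(str(d / "matrix.mtx"), X.T.astype(int), field="integer")
    pd.Series(adata.var_names).to_csv(d / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)


def read_marker_reference(path) -> dict[str, set[str]]:
    """TSV with columns (cell_type, gene) -> {cell type: set of marker genes}."""
    df = pd.read_csv(path, sep="\t")
    if not {"cell_type", "gene"} <= set(df.columns):
        raise ValueError("marker reference needs 'cell_type' and 'gene' columns")
    ref = {t: set(sub["gene"].astype(str)) for t, sub in df.groupby("cell_type")}
    if any(not genes for genes in ref.values()):
        raise ValueError("every cell type needs at least one marker")
    return ref


def write_marker_reference(ref: dict[str, set[str]], path) -> None:
    rows = [(t, g) for t, genes in sorted(ref.items()) for g in sorted(genes)]
    pd.DataFrame(rows, columns=["cell_type", "gene"]).to_csv(path, sep="\t", index=False)
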