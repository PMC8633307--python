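"""Single-cell RNA-seq processing: QC, normalization, clustering, profiles.

The stage mirrors the standard droplet-scRNA workflow: per-cell quality
control (detected genes, library size, mitochondrial fraction), library-size
log-normalization, variance-stabilized selection of highly variable genes,
covariate-regressed z-scaling, PCA, shared-nearest-neighbor graph clustering
(Leiden modularity), marker detection by rank-sum test, marker-reference cell
type assignment with doublet-cluster discard, and finally per-cell-type
expression profiles (the dot-plot statistics: mean log-normalized expression
and percent of cells expressing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "QCConfig",
    "PipelineConfig",
    "CellTypeProfile",
    "qc_metrics",
    "qc_filter_cells",
    "log_normalize",
    "select_hvgs",
    "scale_and_regress",
    "run_pca",
    "build_snn_and_cluster",
    "compute_umap",
    "find_markers",
    "assign_cell_types",
    "aggregate_profiles",
    "run_scrna_pipeline",
]

MITO_PREFIX = "MT-"


@dataclass(frozen=True)
class QCConfig:
    """Per-cell quality-control thresholds.

    All comparisons are strict: a cell with exactly ``min_genes`` detected
    genes, exactly ``min_umi``/``max_umi`` total counts, or exactly
    ``max_mito_frac`` mitochondrial fraction is retained.
    """

    min_genes: int = 400
    min_umi: int = 600
    max_umi: int = 10_000
    max_mito_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.min_umi >= self.max_umi:
            raise ValueError("min_umi must be < max_umi")
        if not (0.0 < self.max_mito_frac <= 1.0):
            raise ValueError("max_mito_frac must be in (0, 1]")


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the normalization/clustering stage.

    ``n_hvgs`` is dataset-dependent (2000 for the mouse kidney reference
    setting, 3000 otherwise); ``snn_k`` is the k of the kNN graph underlying
    the shared-nearest-neighbor weights.
    """

    n_hvgs: int = 2000
    scale_factor: float = 10_000.0
    regress_covariates: tuple[str, ...] = ("mito_fraction", "total_umi")
    clip_max: float = 10.0
    n_pcs: int = 40
    snn_k: int = 20
    resolution: float = 0.5
    umap_neighbors: int = 40
    umap_min_dist: float = 0.3
    marker_min_pct: float = 0.3
    marker_logfc: float = 0.6
    doublet_min_markers: int = 2
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hvgs", "n_pcs", "snn_k", "umap_neighbors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


def _dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def qc_metrics(adata: ad.AnnData) -> ad.AnnData:
    """Annotate per-cell n_genes_detected, total_umi and mito_fraction in obs."""
    X = _dense(adata.X)
    mito = np.array([g.upper().startswith(MITO_PREFIX) for g in adata.var_names])
    total = X.sum(axis=1)
    adata.obs["n_genes_detected"] = (X > 0).sum(axis=1)
    adata.obs["total_umi"] = total
    with np.errstate(invalid="ignore", divide="ignore"):
        mf = np.where(total > 0, X[:, mito].sum(axis=1) / np.maximum(total, 1), 0.0)
    adata.obs["mito_fraction"] = mf
    adata.var["is_mito"] = mito
    return adata


def qc_filter_cells(
    adata: ad.AnnData, qc: QCConfig | None = None
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Discard low-quality cells; return (filtered matrix, per-cell verdicts).

    The verdict table carries one row per input cell with boolean reason
    columns (genes_low, umi_low, umi_high, mito_high) and the overall call, so
    retained + discarded always partition the input.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    qc = qc or QCConfig()
    adata = qc_metrics(adata.copy())
    obs = adata.obs
    verdict = pd.DataFrame(
        {
            "genes_low": obs["n_genes_detected"] < qc.min_genes,
            "umi_low": obs["total_umi"] < qc.min_umi,
            "umi_high": obs["total_umi"] > qc.max_umi,
            "mito_high": obs["mito_fraction"] > qc.max_mito_frac,
        },
        index=obs.index,
    )
    verdict["discarded"] = verdict.any(axis=1)
    verdict["reasons"] = verdict[["genes_low", "umi_low", "umi_high", "mito_high"]].apply(
        lambda r: ";".join(r.index[r]), axis=1
    )
    return adata[~verdict["discarded"].values].copy(), verdict


def log_normalize(adata: ad.AnnData, scale_factor: float = 10_000.0) -> ad.AnnData:
    """Library-size normalize then log1p: log(1 + scale_factor * x / total).

    Stores the result in ``adata.layers['lognorm']``.  Per cell, the sum of
    exp(value) - 1 over genes equals ``scale_factor`` exactly.
    """
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("cell with zero total counts; run QC first")
    adata.layers["lognorm"] = np.log1p(scale_factor * X / totals[:, None])
    adata.uns["scale_factor"] = scale_factor
    return adata


def select_hvgs(adata: ad.AnnData, n_hvgs: int, lowess_frac: float = 0.3) -> list[str]:
    """Rank genes by standardized variance (the "vst" criterion); return top n.

    A lowess curve of log10(variance) on log10(mean) over the raw counts gives
    each gene an expected standard deviation; counts standardized by it and
    clipped at sqrt(n_cells) are re-scored by their variance.  Genes with zero
    count variance rank last.
    """
    if n_hvgs > adata.n_vars:
        raise ValueError(f"n_hvgs={n_hvgs} exceeds n_genes={adata.n_vars}")
    X = _dense(adata.X).astype(float)
    n_cells = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    score = np.zeros(adata.n_vars)
    usable = (mean > 0) & (var > 0)
    if usable.sum() >= 3:
        lm, lv = np.log10(mean[usable]), np.log10(var[usable])
        fit = lowess(lv, lm, frac=lowess_frac, return_sorted=False)
        exp_sd = np.sqrt(10.0**fit)
        clip = np.sqrt(n_cells)
        Z = np.clip((X[:, usable] - mean[usable]) / exp_sd, -clip, clip)
        score[usable] = Z.var(axis=0, ddof=1)
    order = np.lexsort((adata.var_names, -score))  # ties broken alphabetically
    ranked = [adata.var_names[i] for i in order]
    adata.var["hvg_score"] = score
    adata.var["highly_variable"] = adata.var_names.isin(ranked[:n_hvgs])
    return ranked[:n_hvgs]


def scale_and_regress(
    adata: ad.AnnData,
    genes: list[str] | None = None,
    covariates: tuple[str, ...] = ("mito_fraction", "total_umi"),
    clip_max: float = 10.0,
) -> np.ndarray:
    """Regress per-cell covariates out of log-normalized expression, then z-score.

    Per gene: OLS of expression on the covariates (plus intercept); residuals
    are centered, scaled to unit variance and clipped at +/- ``clip_max``.
    Constant covariates are dropped with a warning, so the operation degrades
    to plain z-scoring when no covariate varies.  Returns cells x genes.
    """
    Y = adata.layers["lognorm"]
    if genes is not None:
        idx = adata.var_names.get_indexer(genes)
        if np.any(idx < 0):
            raise KeyError("gene not found in matrix")
        Y = Y[:, idx]
    Y = np.asarray(Y, dtype=float)
    cols = [np.ones(adata.n_obs)]
    for name in covariates:
        c = adata.obs[name].to_numpy(dtype=float)
        if np.std(c) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=2)
            continue
        cols.append(c)
    D = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    resid -= resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return np.clip(resid / sd, -clip_max, clip_max)


def run_pca(scaled: np.ndarray, n_pcs: int, seed: int = 0) -> np.ndarray:
    """Top principal components of the scaled matrix (cells x n_pcs).

    Sign is fixed by forcing the largest-magnitude loading of each component
    positive, so repeated runs agree exactly.
    """
    if n_pcs > min(scaled.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank bound {min(scaled.shape)}")
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    emb = pca.fit_transform(scaled)
    for j in range(n_pcs):
        k = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, k] < 0:
            emb[:, j] *= -1.0
            pca.components_[j] *= -1.0
    return emb


def snn_graph(embeddings: np.ndarray, k: int) -> igraph.Graph:
    """Shared-nearest-neighbor graph: Jaccard overlap of k-NN sets as weights.

    Each cell's neighbor set includes itself; edges with zero overlap are
    absent.
    """
    n = embeddings.shape[0]
    if n <= k:
        raise ValueError(f"need more cells than snn_k={k}")
    nn = NearestNeighbors(n_neighbors=k).fit(embeddings)
    _, idx = nn.kneighbors(embeddings)
    neigh = [set(row) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[j])
            if inter:
                union = len(neigh[i] | neigh[j])
                edges.append((i, int(j)))
                weights.append(inter / union)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def build_snn_and_cluster(
    embeddings: np.ndarray, snn_k: int = 20, resolution: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Cluster cells: kNN -> SNN Jaccard weights -> Leiden modularity communities."""
    g = snn_graph(embeddings, snn_k)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership, dtype=int)


def compute_umap(
    embeddings: np.ndarray, n_neighbors: int = 40, min_dist: float = 0.3, seed: int = 0
) -> np.ndarray:
    """2-D UMAP layout of the PCA embedding (visualization only)."""
    import umap  # deferred: numba compilation is slow at import

    reducer = umap.UMAP(
        n_neighbors=min(n_neighbors, embeddings.shape[0] - 1),
        min_dist=min_dist,
        n_components=2,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(embeddings))


def _log_fc(mean_in: np.ndarray, mean_out: np.ndarray) -> np.ndarray:
    # natural log of (mean expm1 expression + 1) ratio, in-cluster vs rest
    return np.log((mean_in + 1.0) / (mean_out + 1.0))


def find_markers(
    adata: ad.AnnData,
    labels,
    min_pct: float = 0.3,
    logfc_threshold: float = 0.6,
) -> pd.DataFrame:
    """Per-cluster marker genes gated on expression fraction and fold change.

    A gene is a marker of cluster c when expressed (count > 0) in at least
    ``min_pct`` of c's cells and its log fold-change (natural log of mean
    de-logged expression + 1, in-cluster vs all other cells) is at least
    ``logfc_threshold``.  Markers are ranked by two-sided rank-sum p-value of
    log-normalized expression in-cluster vs rest.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("marker detection needs at least two clusters")
    L = np.asarray(adata.layers["lognorm"], dtype=float)
    expm = np.expm1(L)
    detected = L > 0
    rows = []
    for c in uniq:
        mask = labels == c
        pct_in = detected[mask].mean(axis=0)
        lfc = _log_fc(expm[mask].mean(axis=0), expm[~mask].mean(axis=0))
        gate = (pct_in >= min_pct) & (lfc >= logfc_threshold)
        if not gate.any():
            continue
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(
                L[mask][:, gate], L[~mask][:, gate], alternative="two-sided", axis=0
            )
        sub = pd.DataFrame(
            {
                "cluster": c,
                "gene": adata.var_names[gate],
                "pct_in": pct_in[gate],
                "pct_out": detected[~mask].mean(axis=0)[gate],
                "log_fc": lfc[gate],
                "p_value": np.atleast_1d(res.pvalue),
            }
        )
        rows.append(sub.sort_values(["p_value", "gene"]))
    if not rows:
        return pd.DataFrame(
            columns=["cluster", "gene", "pct_in", "pct_out", "log_fc", "p_value"]
        )
    return pd.concat(rows, ignore_index=True)


def assign_cell_types(
    markers: pd.DataFrame,
    reference: dict[str, set[str]],
    doublet_min_markers: int = 2,
    overrides: dict | None = None,
) -> tuple[dict, dict]:
    """Map clusters to reference cell types by marker overlap; flag doublets.

    Each cluster is scored per type by how many of that type's canonical
    markers appear among the cluster's markers and assigned the best-scoring
    type.  A cluster showing at least ``doublet_min_markers`` canonical
    markers of two or more types is flagged a doublet (to be discarded).
    Clusters matching no type are labeled ``"unknown"`` with a warning.
    ``overrides`` maps cluster -> type and bypasses scoring (manual curation).
    """
    if not reference or any(not g for g in reference.values()):
        raise ValueError("marker reference must be nonempty per type")
    overrides = overrides or {}
    assignment: dict = {}
    doublet: dict = {}
    for c, sub in markers.groupby("cluster"):
        genes = set(sub["gene"])
        scores = {t: len(genes & set(ms)) for t, ms in reference.items()}
        strong = [t for t, s in scores.items() if s >= doublet_min_markers]
        doublet[c] = len(strong) >= 2
        if c in overrides:
            assignment[c] = overrides[c]
            doublet[c] = False
            continue
        best = max(scores.values())
        if best == 0:
            warnings.warn(f"cluster {c} matches no reference cell type", stacklevel=2)
            assignment[c] = "unknown"
        else:
            assignment[c] = min(t for t, s in scores.items() if s == best)
    return assignment, doublet


@dataclass
class CellTypeProfile:
    """Dot-plot statistics: per (gene, cell type) mean expression and pct on.

    ``mean_expr``: genes x types mean log-normalized expression.
    ``pct``:       genes x types fraction of cells with count > 0.
    """

    mean_expr: pd.DataFrame
    pct: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.mean_expr.index.equals(self.pct.index) or not self.mean_expr.columns.equals(
            self.pct.columns
        ):
            raise ValueError("mean_expr and pct must share genes and cell types")
        vals = self.pct.to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("pct_expressing must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_expr.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.mean_expr.index)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (gene, cell_type, mean_norm_expr, pct_expressing) table."""
        m = self.mean_expr.stack().rename("mean_norm_expr")
        p = self.pct.stack().rename("pct_expressing")
        out = pd.concat([m, p], axis=1).reset_index()
        out.columns = ["gene", "cell_type", "mean_norm_expr", "pct_expressing"]
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellTypeProfile":
        m = df.pivot(index="gene", columns="cell_type", values="mean_norm_expr")
        p = df.pivot(index="gene", columns="cell_type", values="pct_expressing")
        return cls(m, p.loc[m.index, m.columns])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "CellTypeProfile":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def aggregate_profiles(adata: ad.AnnData, type_labels) -> CellTypeProfile:
    """Aggregate log-normalized expression into per-cell-type profiles.

    ``type_labels`` gives one cell type per retained cell; cells labeled None
    or NaN (e.g. members of discarded doublet clusters) are excluded.  Empty
    types are dropped with a warning.
    """
    labels = pd.Series(np.asarray(type_labels, dtype=object), index=adata.obs_names)
    keep = labels.notna().to_numpy()
    if keep.sum() == 0:
        raise ValueError("no typed cells to aggregate")
    L = np.asarray(adata.layers["lognorm"], dtype=float)[keep]
    X = _dense(adata.X)[keep]
    labels = labels[keep]
    means, pcts = {}, {}
    for t, idx in labels.groupby(labels).groups.items():
        pos = labels.index.get_indexer(idx)
        means[str(t)] = L[pos].mean(axis=0)
        pcts[str(t)] = (X[pos] > 0).mean(axis=0)
    genes = pd.Index(adata.var_names, name="gene")
    cols = sorted(means)
    return CellTypeProfile(
        pd.DataFrame({c: means[c] for c in cols}, index=genes),
        pd.DataFrame({c: pcts[c] for c in cols}, index=genes),
    )


@dataclass
class ScrnaResult:
    adata: ad.AnnData
    qc_verdicts: pd.DataFrame
    hvgs: list[str]
    embeddings: np.ndarray
    clusters: np.ndarray
    markers: pd.DataFrame
    cluster_types: dict
    doublet_clusters: dict
    profile: CellTypeProfile
    umap: np.ndarray | None = None


def run_scrna_pipeline(
    adata: ad.AnnData,
    marker_reference: dict[str, set[str]],
    qc: QCConfig | None = None,
    cfg: PipelineConfig | None = None,
    compute_embedding: bool = False,
) -> ScrnaResult:
    """QC -> normalize -> HVGs -> scale/regress -> PCA -> SNN clustering ->
    markers -> cell-type assignment (doublet discard) -> cell-type profiles."""
    qc = qc or QCConfig()
    cfg = cfg or PipelineConfig()
    filtered, verdicts = qc_filter_cells(adata, qc)
    filtered = log_normalize(filtered, cfg.scale_factor)
    hvgs = select_hvgs(filtered, min(cfg.n_hvgs, filtered.n_vars))
    scaled = scale_and_regress(
        filtered, genes=hvgs, covariates=cfg.regress_covariates, clip_max=cfg.clip_max
    )
    n_pcs = min(cfg.n_pcs, min(scaled.shape) - 1)
    emb = run_pca(scaled, n_pcs, seed=cfg.random_seed)
    clusters = build_snn_and_cluster(
        emb, snn_k=cfg.snn_k, resolution=cfg.resolution, seed=cfg.random_seed
    )
    markers = find_markers(filtered, clusters, cfg.marker_min_pct, cfg.marker_logfc)
    types, doublets = assign_cell_types(markers, marker_reference, cfg.doublet_min_markers)
    type_labels = [
        None if doublets.get(c, False) else types.get(c) for c in clusters
    ]
    filtered.obs["cluster"] = pd.Categorical(clusters)
    filtered.obs["cell_type"] = [t if t is not None else np.nan for t in type_labels]
    profile = aggregate_profiles(filtered, type_labels)
    coords = None
    if compute_embedding:
        coords = compute_umap(emb, cfg.umap_neighbors, cfg.umap_min_dist, cfg.random_seed)
        filtered.obsm["X_umap"] = coords
    return ScrnaResult(
        filtered, verdicts, hvgs, emb, clusters, markers, types, doublets, profile, coords
    )
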