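"""Normalization, variable-gene selection, PCA with permutation-based PC
significance, shared-nearest-neighbor clustering, and UMAP embedding.

The workflow mirrors the standard Seurat-style recipe: counts are
library-size normalized to a fixed scale factor and log-transformed
(natural log1p), the top highly variable genes are selected by
trend-corrected standardized dispersion, genes are centered/scaled before
PCA, and the number of informative PCs is chosen by a jackstraw
permutation test that stops at the first non-significant component.
Clustering builds a k-nearest-neighbor graph on the retained PC scores,
re-weights edges by Jaccard overlap of neighborhoods (pruning weak edges),
and runs modularity community detection (Louvain by default, Leiden
optionally) at a given resolution.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "PCAResult",
    "ClusterAssignment",
    "log_normalize",
    "select_hvgs",
    "scale_matrix",
    "run_pca",
    "jackstraw_select_pcs",
    "cluster_snn",
    "umap_embed",
]


def log_normalize(adata: AnnData, scale_factor: float = 1e4) -> AnnData:
    """ln(1 + count / cell_total * scale_factor), counts kept in
    ``layers['counts']``.  Zero-total cells map to all-zero vectors."""
    out = adata.copy()
    X = sp.csr_matrix(out.X).astype(float)
    out.layers["counts"] = X.copy()
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} cell(s) have zero total counts; normalized to zeros")
    inv = np.divide(scale_factor, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0)
    X = sp.diags(inv) @ X
    X.data = np.log1p(X.data)
    out.X = sp.csr_matrix(X)
    out.uns["scale_factor"] = scale_factor
    return out


def select_hvgs(adata_norm: AnnData, n: int = 2000) -> list[str]:
    """Top ``n`` highly variable genes by mean-binned standardized
    dispersion of the log-normalized data (Seurat-style), deterministic
    with ties broken by gene id."""
    import scanpy as sc

    if n >= adata_norm.n_vars:
        if n > adata_norm.n_vars:
            warnings.warn(f"requested {n} HVGs but only {adata_norm.n_vars} genes present; returning all")
        n = adata_norm.n_vars
    tmp = adata_norm.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(tmp, flavor="seurat", n_top_genes=min(n, tmp.n_vars))
    disp = tmp.var["dispersions_norm"].fillna(-np.inf)
    order = sorted(adata_norm.var_names, key=lambda g: (-disp[g], g))
    return order[:n]


def scale_matrix(adata_norm: AnnData, genes: list[str], max_value: float = 10.0) -> np.ndarray:
    """Dense per-gene z-scored matrix over the given genes, clipped at
    ``max_value`` (Seurat ScaleData convention)."""
    X = np.asarray(sp.csr_matrix(adata_norm[:, genes].X).todense())
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return np.clip((X - mu) / sd, -max_value, max_value)


@dataclass
class PCAResult:
    scores: np.ndarray  # cells x n_pcs
    loadings: np.ndarray  # genes x n_pcs
    variance_explained: np.ndarray
    genes: list[str]
    jackstraw_p: np.ndarray | None = None
    n_selected: int | None = None


def run_pca(adata_norm: AnnData, genes: list[str], n_pcs: int = 50, seed: int = 0) -> PCAResult:
    Z = scale_matrix(adata_norm, genes)
    n_pcs = min(n_pcs, min(Z.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(Z)
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        variance_explained=pca.explained_variance_ratio_,
        genes=list(genes),
    )


def _select_until_first_nonsignificant(pvals: np.ndarray, alpha: float) -> int:
    n = 0
    for p in pvals:
        if p < alpha:
            n += 1
        else:
            break
    return n


def jackstraw_select_pcs(
    adata_norm: AnnData,
    hvgs: list[str],
    max_pcs: int = 20,
    prop: float = 0.05,
    n_reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    min_pcs: int = 0,
    gene_p_threshold: float = 1e-3,
) -> PCAResult:
    """Permutation test for PC significance (jackstraw).

    In each replicate a random proportion ``prop`` of the variable genes
    is permuted across cells and PCA is re-run; the absolute loadings of
    permuted genes form the per-PC null.  Each gene gets an empirical
    p-value per PC, and the per-PC p-value is a one-sided binomial test of
    whether more genes than expected fall below ``gene_p_threshold``.
    The threshold is deliberately extreme: because every observed gene
    also participates in defining the PCs, moderate gene-level p-values
    are slightly inflated on pure noise, while the far tail stays
    calibrated.  When the pooled null is too small to resolve the
    threshold it is widened to ``2 / (null size + 1)`` with a warning.
    ``n_selected`` is the run of significant PCs up to the first
    non-significant one.  Raises when no PC is significant unless
    ``min_pcs`` forces a minimum (``min_pcs`` also acts as a floor, since
    graph clustering degenerates on a 1-D embedding).
    """
    from scipy.stats import binomtest

    rng = np.random.default_rng(seed)
    Z = scale_matrix(adata_norm, hvgs)
    n_cells, n_genes = Z.shape
    max_pcs = min(max_pcs, min(Z.shape) - 1)
    pca = PCA(n_components=max_pcs, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # genes x pcs
    obs_stat = np.abs(loadings)

    n_perm = max(1, int(round(prop * n_genes)))
    null = [[] for _ in range(max_pcs)]
    for _ in range(n_reps):
        idx = rng.choice(n_genes, size=n_perm, replace=False)
        Zp = Z.copy()
        for j in idx:
            Zp[:, j] = Zp[rng.permutation(n_cells), j]
        rep_pca = PCA(n_components=max_pcs, svd_solver="randomized", random_state=seed)
        rep_pca.fit(Zp)
        rep_load = np.abs(rep_pca.components_.T[idx])  # permuted genes x pcs
        for pc in range(max_pcs):
            null[pc].append(rep_load[:, pc])
    n_null = n_perm * n_reps
    gene_thresh = gene_p_threshold
    if gene_thresh < 2.0 / (n_null + 1):
        gene_thresh = 2.0 / (n_null + 1)
        warnings.warn(
            f"permutation null too small for gene_p_threshold={gene_p_threshold:g}; "
            f"using {gene_thresh:.2g} (raise prop or n_reps to sharpen)"
        )
    pc_p = np.empty(max_pcs)
    for pc in range(max_pcs):
        null_pc = np.sort(np.concatenate(null[pc]))
        # empirical gene-level p-values against the permutation null
        ranks = np.searchsorted(null_pc, obs_stat[:, pc], side="left")
        gene_p = (1.0 + null_pc.size - ranks) / (1.0 + null_pc.size)
        k = int((gene_p < gene_thresh).sum())
        pc_p[pc] = binomtest(k, n_genes, gene_thresh, alternative="greater").pvalue

    n_selected = _select_until_first_nonsignificant(pc_p, alpha)
    if n_selected == 0 and min_pcs == 0:
        raise ValueError(
            "no principal component is significant; pass min_pcs >= 2 to force a minimum"
        )
    # min_pcs acts as a floor: graph clustering degenerates on a 1-D embedding
    n_selected = min(max(n_selected, min_pcs), max_pcs)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_explained=pca.explained_variance_ratio_,
        genes=list(hvgs),
        jackstraw_p=pc_p,
        n_selected=n_selected,
    )


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    resolution: float
    k_neighbors: int
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def snn_graph(scores: np.ndarray, k: int = 20, prune: float = 1 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of k-NN sets
    (self-inclusive), entries below ``prune`` removed."""
    n = scores.shape[0]
    if k > n:
        warnings.warn(f"k={k} exceeds number of cells {n}; reducing")
        k = n
    nn = NearestNeighbors(n_neighbors=k).fit(scores)
    A = nn.kneighbors_graph(scores, mode="connectivity")  # includes self
    shared = (A @ A.T).tocoo()
    union = 2 * k - shared.data
    jacc = shared.data / union
    keep = jacc >= prune
    W = sp.csr_matrix((jacc[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    W.setdiag(0)
    W.eliminate_zeros()
    return W


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    # contiguous ids, largest cluster first; ties by original id for determinism
    counts = pd.Series(labels).value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[c] for c in labels])


def cluster_snn(
    pca: PCAResult | np.ndarray,
    k: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    prune: float = 1 / 15,
    algorithm: str = "louvain",
) -> ClusterAssignment:
    """Modularity community detection on the SNN graph of PC scores."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if isinstance(pca, PCAResult):
        npc = pca.n_selected or pca.scores.shape[1]
        scores = pca.scores[:, :npc]
    else:
        scores = np.asarray(pca)
    W = snn_graph(scores, k=min(k, scores.shape[0]), prune=prune)
    sources, targets = sp.triu(W, k=1).nonzero()
    weights = np.asarray(W[sources, targets]).ravel()
    g = ig.Graph(n=W.shape[0], edges=list(zip(sources.tolist(), targets.tolist())))
    if algorithm == "louvain":
        random.seed(seed)
        part = g.community_multilevel(weights=weights.tolist(), resolution=resolution)
        labels = np.array(part.membership)
    elif algorithm == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights.tolist(),
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        labels = np.array(part.membership)
    else:
        raise ValueError(f"unknown algorithm '{algorithm}'")
    return ClusterAssignment(
        labels=_relabel_by_size(labels), resolution=resolution, k_neighbors=k, seed=seed
    )


def umap_embed(pca: PCAResult, seed: int = 0, n_neighbors: int = 30, min_dist: float = 0.3) -> np.ndarray:
    """2-D UMAP coordinates of the retained PC scores, seed-reproducible."""
    import umap

    npc = pca.n_selected or pca.scores.shape[1]
    scores = pca.scores[:, :npc]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, scores.shape[0] - 1),
            min_dist=min_dist,
            random_state=seed,
        )
        return reducer.fit_transform(scores)
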