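"""Targeted subclustering: subset cells by cluster membership and
gene-expression predicates, then re-run PCA / PC selection / clustering /
marker detection on the subset.

Normalization is inherited from the parent analysis (only the PCA and
everything downstream of it is recomputed), mirroring how focused
re-analyses of doublesex-expressing, Kenyon-cell, and circadian clusters
are usually performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .embed import cluster_snn, jackstraw_select_pcs, run_pca, select_hvgs
from .markers import MarkerTable, find_markers
from .sexbias import sex_counts_per_cluster

__all__ = ["SubclusterSpec", "SubclusterResult", "subset_and_recluster", "builtin_specs"]


@dataclass
class SubclusterSpec:
    """Which cells to keep and how to recluster them.

    ``gene_predicates`` are conjuncts (gene, min_umis): a cell passes when
    every listed gene has raw UMIs >= min_umis.  ``n_pcs`` is either a
    fixed integer or the string ``"jackstraw"`` to reselect significant
    PCs on the subset.
    """

    name: str
    source_clusters: set = field(default_factory=set)
    gene_predicates: list[tuple[str, int]] = field(default_factory=list)
    n_pcs: int | str = "jackstraw"
    resolution: float = 0.5
    n_hvg: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass
class SubclusterResult:
    spec: SubclusterSpec
    cell_names: list[str]
    labels: np.ndarray
    markers: MarkerTable
    sex_counts: pd.DataFrame
    n_pcs_used: int


def _select_cells(adata: AnnData, labels: np.ndarray, spec: SubclusterSpec) -> np.ndarray:
    mask = np.isin(labels, list(spec.source_clusters)) if spec.source_clusters else np.ones(adata.n_obs, bool)
    counts = sp.csr_matrix(adata.layers.get("counts", adata.X))
    for gene, min_umis in spec.gene_predicates:
        if gene not in adata.var_names:
            raise ValueError(f"predicate gene '{gene}' not in matrix")
        col = np.asarray(counts[:, adata.var_names.get_loc(gene)].todense()).ravel()
        new = mask & (col >= min_umis)
        if not new.any():
            raise ValueError(f"predicate ({gene} >= {min_umis}) leaves no cells")
        mask = new
    return mask


def subset_and_recluster(
    adata_norm: AnnData,
    labels: np.ndarray | pd.Series,
    spec: SubclusterSpec,
    min_cells: int = 10,
    max_pcs: int = 20,
) -> SubclusterResult:
    """Subset per ``spec`` and re-run HVG selection, PCA, PC selection,
    SNN clustering, and marker detection on the subset.

    The parent's log-normalization is reused.  Raises when the selection
    yields fewer than ``min_cells`` cells.
    """
    labels = np.asarray(labels)
    mask = _select_cells(adata_norm, labels, spec)
    if mask.sum() < min_cells:
        raise ValueError(f"subcluster selection yields only {int(mask.sum())} cells (< {min_cells})")
    sub = adata_norm[mask].copy()

    hvgs = select_hvgs(sub, n=min(spec.n_hvg, sub.n_vars))
    if spec.n_pcs == "jackstraw":
        pca = jackstraw_select_pcs(sub, hvgs, max_pcs=min(max_pcs, sub.n_obs - 1), seed=spec.seed, min_pcs=2)
    else:
        pca = run_pca(sub, hvgs, n_pcs=int(spec.n_pcs), seed=spec.seed)
        pca.n_selected = min(int(spec.n_pcs), pca.scores.shape[1])
    assignment = cluster_snn(pca, resolution=spec.resolution, seed=spec.seed, k=min(20, sub.n_obs - 1))

    if assignment.n_clusters >= 2:
        markers = find_markers(sub, assignment.labels)
    else:
        markers = MarkerTable(
            pd.DataFrame(columns=["cluster", "gene", "p_raw", "p_bonf", "log_fc", "pct_in", "pct_out"]),
            min_pct=0.25, logfc_threshold=0.25, alpha=0.05,
        )
    sex_counts = sex_counts_per_cluster(assignment.labels, sub.obs["sex"].to_numpy())
    return SubclusterResult(
        spec=spec,
        cell_names=list(sub.obs_names),
        labels=assignment.labels,
        markers=markers,
        sex_counts=sex_counts,
        n_pcs_used=pca.n_selected or pca.scores.shape[1],
    )


def builtin_specs(
    dsx_clusters: set = frozenset({21, 47, 68}),
    kc_clusters: set = frozenset(),
    circadian_clusters: set = frozenset(),
) -> dict[str, SubclusterSpec]:
    """The three stock subclustering configurations.

    * ``dsx``: doublesex-enriched male-specific/biased clusters, keeping
      only cells with dsx UMIs > 0, 27 fixed PCs, resolution 0.5.
    * ``kc``: high-confidence Kenyon-cell clusters, 21 fixed PCs,
      resolution 0.5.
    * ``circadian``: circadian-annotated clusters, 2 fixed PCs,
      resolution 2.5.

    The fixed PC counts reflect the reference atlas analysis; on other
    data pass ``n_pcs="jackstraw"`` to reselect.  Cluster id sets for
    ``kc`` and ``circadian`` come from the annotation step, so they are
    parameters here.
    """
    return {
        "dsx": SubclusterSpec(
            name="dsx",
            source_clusters=set(dsx_clusters),
            gene_predicates=[("dsx", 1)],
            n_pcs=27,
            resolution=0.5,
        ),
        "kc": SubclusterSpec(name="kc", source_clusters=set(kc_clusters), n_pcs=21, resolution=0.5),
        "circadian": SubclusterSpec(
            name="circadian", source_clusters=set(circadian_clusters), n_pcs=2, resolution=2.5
        ),
    }
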