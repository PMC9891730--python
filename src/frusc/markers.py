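"""Cluster marker-gene detection and within-cluster sex-differential
expression by Wilcoxon rank-sum testing.

A gene is a candidate marker for a cluster when it is detected (raw
UMIs > 0) in at least ``min_pct`` of cells in either the cluster or the
rest, and its natural-log fold change of de-logged mean expression
(pseudocount 1) is at least ``logfc_threshold``.  Candidates are tested
two-sided (cluster vs all remaining cells) on log-normalized values;
p-values are Bonferroni-corrected over all genes in the matrix.  Only
positively enriched genes are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import mannwhitneyu

__all__ = [
    "MarkerTable",
    "ranksum_p",
    "log_fold_change",
    "find_markers",
    "find_sex_de_within_cluster",
    "top_markers",
]

MARKER_COLUMNS = ["cluster", "gene", "p_raw", "p_bonf", "log_fc", "pct_in", "pct_out"]


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value: exact for small tie-free
    samples (both n <= 8), otherwise normal approximation with mid-rank
    tie correction and no continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) <= 8 and len(y) <= 8
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    return float(res.pvalue)


def log_fold_change(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """ln((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1)) on
    log-normalized values — the Seurat fold-change convention in natural
    log units."""
    return float(np.log((np.expm1(x_in).mean() + 1.0) / (np.expm1(x_out).mean() + 1.0)))


@dataclass
class MarkerTable:
    """Per-cluster enriched genes with test statistics and thresholds used."""

    records: pd.DataFrame
    min_pct: float
    logfc_threshold: float
    alpha: float
    p_filter: str = "raw"  # significance judged on 'raw' or 'bonferroni' p

    def for_cluster(self, cluster) -> pd.DataFrame:
        return self.records[self.records["cluster"] == cluster]

    @property
    def genes_by_cluster(self) -> dict:
        return {c: set(df["gene"]) for c, df in self.records.groupby("cluster", observed=True)}


def _dense_col(X: sp.csr_matrix, j: int) -> np.ndarray:
    return np.asarray(X[:, j].todense()).ravel()


def _marker_scan(
    norm: np.ndarray,
    detected: np.ndarray,
    in_mask: np.ndarray,
    genes: np.ndarray,
    n_genes_total: int,
    min_pct: float,
    logfc_threshold: float,
    alpha: float,
    p_filter: str,
    cluster_id,
) -> list[dict]:
    """One cluster-vs-rest scan. ``norm``: dense cells x genes block of
    log-normalized values; ``detected``: same-shape boolean raw-count>0."""
    out_mask = ~in_mask
    pct_in = detected[in_mask].mean(axis=0)
    pct_out = detected[out_mask].mean(axis=0)
    mean_exp_in = np.expm1(norm[in_mask]).mean(axis=0)
    mean_exp_out = np.expm1(norm[out_mask]).mean(axis=0)
    log_fc = np.log((mean_exp_in + 1.0) / (mean_exp_out + 1.0))
    candidates = np.flatnonzero(
        (np.maximum(pct_in, pct_out) >= min_pct) & (log_fc >= logfc_threshold)
    )
    records = []
    for j in candidates:
        p = ranksum_p(norm[in_mask, j], norm[out_mask, j])
        p_bonf = min(1.0, p * n_genes_total)
        p_used = p if p_filter == "raw" else p_bonf
        if p_used < alpha:
            records.append(
                {
                    "cluster": cluster_id,
                    "gene": genes[j],
                    "p_raw": p,
                    "p_bonf": p_bonf,
                    "log_fc": float(log_fc[j]),
                    "pct_in": float(pct_in[j]),
                    "pct_out": float(pct_out[j]),
                }
            )
    return records


def _as_dense(adata_norm: AnnData) -> tuple[np.ndarray, np.ndarray]:
    norm = np.asarray(sp.csr_matrix(adata_norm.X).todense())
    counts = adata_norm.layers.get("counts")
    detected = (np.asarray(sp.csr_matrix(counts).todense()) > 0) if counts is not None else (norm > 0)
    return norm, detected


def find_markers(
    adata_norm: AnnData,
    labels: np.ndarray | pd.Series,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
    p_filter: str = "raw",
) -> MarkerTable:
    """Enriched markers for every cluster (cluster vs all remaining cells).

    Clusters with fewer than 3 cells are skipped with a warning.
    Detection fractions use raw counts when a ``counts`` layer is present.
    """
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels).tolist())
    if len(clusters) < 2:
        raise ValueError("marker detection requires at least 2 clusters")
    norm, detected = _as_dense(adata_norm)
    genes = np.asarray(adata_norm.var_names)
    records: list[dict] = []
    for c in clusters:
        in_mask = labels == c
        if in_mask.sum() < 3:
            warnings.warn(f"cluster {c} has fewer than 3 cells; skipped")
            continue
        records.extend(
            _marker_scan(
                norm, detected, in_mask, genes, adata_norm.n_vars,
                min_pct, logfc_threshold, alpha, p_filter, c,
            )
        )
    df = pd.DataFrame(records, columns=MARKER_COLUMNS)
    return MarkerTable(df, min_pct=min_pct, logfc_threshold=logfc_threshold, alpha=alpha, p_filter=p_filter)


def find_sex_de_within_cluster(
    adata_norm: AnnData,
    labels: np.ndarray | pd.Series,
    sex: np.ndarray | pd.Series | None = None,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
    p_filter: str = "raw",
) -> pd.DataFrame:
    """Within-cluster sex-biased genes: male cells vs female cells of the
    same cluster, both directions, with the marker filters.  Clusters
    lacking 3 cells of each sex are skipped; the reasons are recorded in
    the ``skipped`` attribute of the returned frame (``df.attrs``)."""
    labels = np.asarray(labels)
    sex = np.asarray(adata_norm.obs["sex"]) if sex is None else np.asarray(sex)
    norm, detected = _as_dense(adata_norm)
    genes = np.asarray(adata_norm.var_names)
    records: list[dict] = []
    skipped: dict = {}
    for c in sorted(pd.unique(labels).tolist()):
        cmask = labels == c
        male = cmask & (sex == "male")
        female = cmask & (sex == "female")
        if male.sum() < 3 or female.sum() < 3:
            skipped[c] = f"needs >=3 cells of each sex (male={int(male.sum())}, female={int(female.sum())})"
            continue
        sub = cmask
        sub_norm, sub_det = norm[sub], detected[sub]
        sub_male = (sex[sub] == "male")
        for direction, in_mask in (("male", sub_male), ("female", ~sub_male)):
            recs = _marker_scan(
                sub_norm, sub_det, in_mask, genes, adata_norm.n_vars,
                min_pct, logfc_threshold, alpha, p_filter, c,
            )
            for r in recs:
                r["direction"] = direction
            records.extend(recs)
    df = pd.DataFrame(records, columns=MARKER_COLUMNS + ["direction"])
    df.attrs["skipped"] = skipped
    return df


def top_markers(table: MarkerTable | pd.DataFrame, n: int = 5, rank_by: str = "log_fc") -> pd.DataFrame:
    """Top-n markers per cluster ranked by ``rank_by`` (descending), ties
    broken by raw p-value then gene id; clusters with fewer than n markers
    return all of them."""
    df = table.records if isinstance(table, MarkerTable) else table
    if df.empty:
        return df.copy()
    ranked = df.sort_values(
        by=[rank_by, "p_raw", "gene"], ascending=[False, True, True], kind="mergesort"
    )
    return ranked.groupby("cluster", observed=True, group_keys=False).head(n).reset_index(drop=True)
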