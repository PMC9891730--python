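"""Downsampling / random-removal robustness analyses and correlation-based
cluster matching between analyses.

To test whether unequal cell numbers between the sexes drive cluster
composition calls, the over-represented sex is randomly downsampled to a
target count (cells removed whole, never thinned), the pipeline is re-run,
and each new cluster is matched back to the reference clustering by
Spearman correlation of mean log-normalized expression profiles over the
reference's variable genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import spearmanr, pearsonr

__all__ = [
    "downsample",
    "cluster_profiles",
    "match_clusters",
    "concordance_report",
    "recount_after_removal",
]


def downsample(
    adata: AnnData,
    target_per_sex: int | dict[str, int],
    seed: int = 0,
) -> AnnData:
    """Uniform random subset without replacement, per sex.

    ``target_per_sex`` may be one integer applied to every sex present or
    a mapping sex -> target.  Targets above the available count raise.
    """
    rng = np.random.default_rng(seed)
    sex = adata.obs["sex"].to_numpy()
    keep = np.zeros(adata.n_obs, dtype=bool)
    sexes = pd.unique(sex).tolist()
    targets = {s: target_per_sex for s in sexes} if isinstance(target_per_sex, int) else dict(target_per_sex)
    for s in sexes:
        idx = np.flatnonzero(sex == s)
        t = targets.get(s, idx.size)
        if t > idx.size:
            raise ValueError(f"target {t} exceeds available {idx.size} cells for sex '{s}'")
        keep[rng.choice(idx, size=t, replace=False)] = True
    return adata[keep].copy()


def cluster_profiles(
    adata_norm: AnnData, labels: np.ndarray | pd.Series, genes: list[str]
) -> pd.DataFrame:
    """Per-cluster mean log-normalized expression over ``genes``
    (clusters x genes)."""
    labels = np.asarray(labels)
    present = [g for g in genes if g in adata_norm.var_names]
    X = np.asarray(sp.csr_matrix(adata_norm[:, present].X).todense())
    rows = {c: X[labels == c].mean(axis=0) for c in sorted(pd.unique(labels).tolist())}
    return pd.DataFrame.from_dict(rows, orient="index", columns=present)


def match_clusters(
    reference: pd.DataFrame,
    query: pd.DataFrame,
    cutoff: float = 0.5,
    method: str = "spearman",
) -> pd.DataFrame:
    """Assign each query cluster to its best-correlated reference cluster.

    ``reference`` and ``query`` are cluster-profile frames
    (clusters x genes, e.g. from :func:`cluster_profiles`); correlation is
    computed over the shared gene columns.  A query cluster is assigned to
    the argmax-correlation reference cluster when rho >= ``cutoff``, else
    left unassigned; ties break by reference cluster id order.
    """
    shared = [g for g in reference.columns if g in query.columns]
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared genes to match clusters, got {len(shared)}")
    fn = spearmanr if method == "spearman" else pearsonr
    rows = []
    for q in query.index:
        best_ref, best_rho = None, -np.inf
        for r in reference.index:
            rho = fn(query.loc[q, shared], reference.loc[r, shared]).statistic
            if np.isnan(rho):
                continue
            if rho > best_rho:
                best_ref, best_rho = r, rho
        assigned = best_ref is not None and best_rho >= cutoff
        rows.append(
            {
                "query_cluster": q,
                "best_reference_cluster": best_ref if assigned else None,
                "rho": best_rho if best_ref is not None else np.nan,
                "assigned": assigned,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["cutoff"] = cutoff
    out.attrs["method"] = method
    return out


def recount_after_removal(
    adata: AnnData,
    labels: np.ndarray | pd.Series,
    target_per_sex: int | dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Random cell removal *without* re-clustering: keep the original
    labels and recount per-cluster sex composition on the subset."""
    from .sexbias import sex_counts_per_cluster

    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    sub = downsample(adata, target_per_sex, seed=seed)
    return sex_counts_per_cluster(labels.loc[sub.obs_names].to_numpy(), sub.obs["sex"].to_numpy())


def concordance_report(
    full_report: pd.DataFrame,
    run_reports: list[pd.DataFrame],
    run_matches: list[pd.DataFrame],
) -> pd.DataFrame:
    """Stability of each reference cluster's sex-bias class across runs.

    ``full_report``: the reference sex-bias report; ``run_reports``: one
    sex-bias report per downsampling run; ``run_matches``: the matching
    table of each run's clusters to reference clusters.  A reference
    cluster is *stable* when every run that matched it assigned the same
    class as the reference; runs with no matching cluster are recorded as
    unmatched.
    """
    full = full_report.set_index("cluster")
    rows = []
    for ref_cluster in full.index:
        ref_class = full.loc[ref_cluster, "class"]
        per_run, changed_runs, unmatched_runs = [], [], []
        for i, (rep, match) in enumerate(zip(run_reports, run_matches)):
            hits = match[(match["assigned"]) & (match["best_reference_cluster"] == ref_cluster)]
            if hits.empty:
                per_run.append(None)
                unmatched_runs.append(i)
                continue
            q = hits.sort_values("rho", ascending=False)["query_cluster"].iloc[0]
            cls = rep.set_index("cluster").loc[q, "class"]
            per_run.append(cls)
            if cls != ref_class:
                changed_runs.append(i)
        rows.append(
            {
                "cluster": ref_cluster,
                "class_full": ref_class,
                "classes_by_run": per_run,
                "stable": not changed_runs and len(unmatched_runs) < len(run_reports),
                "changed_in_runs": changed_runs,
                "unmatched_in_runs": unmatched_runs,
            }
        )
    return pd.DataFrame(rows)
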