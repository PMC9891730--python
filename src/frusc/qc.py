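"""Count-matrix loading, per-cell QC metrics, cell filtering, and
neuron classification.

Filtering reproduces the droplet-QC conventions of Seurat-style workflows:
cells are removed when the mitochondrial UMI fraction exceeds 5%, fewer
than 200 genes are detected (empty droplets), more than 4000 genes are
detected, or more than 20,000 UMIs are present (potential multiplets).
All comparisons are strict inequalities, so boundary cells are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "QCThresholds",
    "load_counts",
    "compute_qc",
    "filter_cells",
    "classify_neurons",
    "DEFAULT_NEURON_GENES",
]

DEFAULT_NEURON_GENES = ("elav", "nSyb", "noe")


@dataclass(frozen=True)
class QCThresholds:
    """Cell-filter cutoffs; a cell is removed when it violates any strict
    inequality (mito > max_mito_fraction, genes < min_genes,
    genes > max_genes, UMIs > max_umis)."""

    max_mito_fraction: float = 0.05
    min_genes: int = 200
    max_genes: int = 4000
    max_umis: int = 20000

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")
        if min(self.max_mito_fraction, self.min_genes, self.max_genes, self.max_umis) <= 0:
            raise ValueError("all QC thresholds must be positive")


def _dedupe(ids: list[str]) -> list[str]:
    # deterministic suffix rule, matching anndata's make-unique convention
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


def load_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path,
) -> AnnData:
    """Read a 10x-style triplet (Matrix Market genes x cells) plus a cell
    metadata TSV with columns barcode, sex, replicate.

    Raises ``ValueError`` on dimension mismatches, non-integer counts, or
    cells missing a sex label (the offending barcode is named).  Duplicate
    gene ids are disambiguated with numeric suffixes.
    """
    M = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if M.shape[0] != len(genes):
        raise ValueError(f"gene table has {len(genes)} entries but matrix has {M.shape[0]} rows")
    if M.shape[1] != len(barcodes):
        raise ValueError(f"barcode table has {len(barcodes)} entries but matrix has {M.shape[1]} columns")
    if M.data.size and (M.data < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(M.data, np.round(M.data)):
        raise ValueError("counts must be integral UMIs")
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcodes must be unique")

    meta = pd.read_csv(meta_path, sep="\t").set_index("barcode")
    for col in ("sex", "replicate"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column '{col}'")
    missing = [b for b in barcodes if b not in meta.index]
    if missing:
        raise ValueError(f"metadata missing for barcode(s): {missing[:5]}")
    meta = meta.loc[barcodes]
    bad_sex = meta.index[~meta["sex"].isin(["male", "female"])]
    if len(bad_sex):
        raise ValueError(f"invalid or missing sex label for barcode(s): {list(bad_sex[:5])}")

    obs = pd.DataFrame(
        {"sex": pd.Categorical(meta["sex"], categories=["male", "female"]), "replicate": meta["replicate"].astype(str)},
        index=barcodes,
    )
    var = pd.DataFrame(index=_dedupe(genes))
    return AnnData(X=sp.csr_matrix(M.T).astype(np.int64), obs=obs, var=var)


def compute_qc(
    adata: AnnData,
    mito_prefix: str = "mt:",
    thresholds: QCThresholds = QCThresholds(),
) -> pd.DataFrame:
    """Per-cell QC report: n_genes detected (UMIs > 0), n_umis,
    mitochondrial UMI fraction (0 for all-zero cells), pass flag and
    fail reasons under the given thresholds."""
    X = sp.csr_matrix(adata.X)
    n_umis = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    mito_mask = np.array([g.startswith(mito_prefix) for g in adata.var_names])
    mito_umis = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros(X.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(n_umis > 0, mito_umis / np.maximum(n_umis, 1), 0.0)

    reasons = []
    for mf, ng, nu in zip(mito_fraction, n_genes, n_umis):
        r = []
        if mf > thresholds.max_mito_fraction:
            r.append("mito")
        if ng < thresholds.min_genes:
            r.append("low_genes")
        if ng > thresholds.max_genes:
            r.append("high_genes")
        if nu > thresholds.max_umis:
            r.append("high_umis")
        reasons.append(",".join(r))
    report = pd.DataFrame(
        {
            "n_genes_detected": n_genes,
            "n_umis": n_umis.astype(np.int64),
            "mito_fraction": mito_fraction,
            "fail_reasons": reasons,
        },
        index=adata.obs_names,
    )
    report["pass"] = report["fail_reasons"] == ""
    return report


def filter_cells(
    adata: AnnData,
    thresholds: QCThresholds = QCThresholds(),
    mito_prefix: str = "mt:",
) -> tuple[AnnData, pd.DataFrame]:
    """Remove cells violating the QC thresholds; returns the kept subset
    and the full per-cell report (including removed cells)."""
    report = compute_qc(adata, mito_prefix=mito_prefix, thresholds=thresholds)
    keep = report["pass"].to_numpy()
    if not keep.any():
        warnings.warn("all cells removed by QC filters")
    return adata[keep].copy(), report


def classify_neurons(
    adata: AnnData, neuron_genes: tuple[str, ...] = DEFAULT_NEURON_GENES
) -> tuple[pd.Series, float]:
    """Flag cells as neurons when any neuronal indicator gene (default
    elav, nSyb, noe) has UMIs > 0; returns (per-cell flags, fraction)."""
    present = [g for g in neuron_genes if g in adata.var_names]
    missing = set(neuron_genes) - set(present)
    if missing:
        warnings.warn(f"neuron indicator gene(s) not in matrix, treated as absent: {sorted(missing)}")
    if present:
        sub = sp.csr_matrix(adata[:, present].X)
        flags = np.asarray((sub > 0).sum(axis=1)).ravel() > 0
    else:
        flags = np.zeros(adata.n_obs, dtype=bool)
    series = pd.Series(flags, index=adata.obs_names, name="is_neuron")
    return series, float(flags.mean()) if adata.n_obs else 0.0
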