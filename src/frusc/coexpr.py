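"""Gene-gene correlations across single cells and co-expression
proportion summaries (Euler-style exclusive overlaps, co-transmission).

Correlations are computed on log-normalized values by default; expression
*membership* for overlap and co-transmission summaries uses raw UMIs > 0,
consistent with the detection convention elsewhere in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "CorrelationMatrix",
    "pairwise_correlation",
    "overlap_proportions",
    "cotransmission",
]


@dataclass
class CorrelationMatrix:
    genes: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    method: str


def _gene_matrix(adata: AnnData, genes: list[str], layer: str | None) -> np.ndarray:
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"gene(s) not in matrix: {missing}")
    idx = [adata.var_names.get_loc(g) for g in genes]
    X = adata.layers[layer] if layer is not None else adata.X
    return np.asarray(sp.csr_matrix(X)[:, idx].todense(), dtype=float)


def pairwise_correlation(
    adata: AnnData,
    genes: list[str],
    method: str = "pearson",
    cells: np.ndarray | pd.Series | None = None,
    layer: str | None = None,
) -> CorrelationMatrix:
    """Pairwise correlations of the given genes over all cells (or the
    boolean/cell-index subset ``cells``) on the matrix ``layer``
    (default: the log-normalized ``X``).

    Constant genes yield undefined correlations, reported as NaN with a
    warning.  Diagonal entries are 1 with p = 0.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got '{method}'")
    sub = adata if cells is None else adata[np.asarray(cells)]
    if sub.n_obs < 3:
        raise ValueError("correlation requires at least 3 cells")
    M = _gene_matrix(sub, genes, layer)
    constant = [g for g, col in zip(genes, M.T) if np.ptp(col) == 0]
    if constant:
        warnings.warn(f"constant gene(s), correlations undefined: {constant}")
    k = len(genes)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    fn = pearsonr if method == "pearson" else spearmanr
    for i in range(k):
        for j in range(i + 1, k):
            if genes[i] in constant or genes[j] in constant:
                continue
            res = fn(M[:, i], M[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(
        genes=list(genes),
        r=pd.DataFrame(r, index=genes, columns=genes),
        p=pd.DataFrame(p, index=genes, columns=genes),
        method=method,
    )


def overlap_proportions(adata: AnnData, trio: tuple[str, str, str]) -> dict:
    """Exclusive overlap fractions for three genes over the cells that
    express at least one of them (raw UMIs > 0): keys ``only_A`` ..
    ``A_B_C`` plus the denominator ``n_expressing``.

    With no expressing cell the proportions are NaN with a warning.
    """
    a, b, c = trio
    M = _gene_matrix(adata, list(trio), layer="counts" if "counts" in adata.layers else None) > 0
    A, B, C = M[:, 0], M[:, 1], M[:, 2]
    expressing = A | B | C
    n = int(expressing.sum())
    keys = {
        f"only_{a}": A & ~B & ~C,
        f"only_{b}": ~A & B & ~C,
        f"only_{c}": ~A & ~B & C,
        f"{a}_{b}": A & B & ~C,
        f"{a}_{c}": A & ~B & C,
        f"{b}_{c}": ~A & B & C,
        f"{a}_{b}_{c}": A & B & C,
    }
    if n == 0:
        warnings.warn("no cell expresses any of the trio; proportions undefined")
        out = {k: float("nan") for k in keys}
    else:
        out = {k: float(v.sum()) / n for k, v in keys.items()}
    out["n_expressing"] = n
    return out


def cotransmission(
    adata: AnnData,
    aminergic_sets: dict[str, list[str]],
    fan_sets: dict[str, list[str]],
    by_sex: bool = True,
) -> pd.DataFrame:
    """Proportion of cells of each aminergic class (any member gene
    detected) that co-express each fast-acting-neurotransmitter class,
    split by sex when ``by_sex``.

    Rows with zero aminergic cells carry NaN proportions and
    ``n_cells = 0`` so they can be flagged downstream.
    """
    from .annotate import classify_cells_by_sets

    amine_flags = classify_cells_by_sets(adata, aminergic_sets)
    fan_flags = classify_cells_by_sets(adata, fan_sets)
    sex = adata.obs["sex"].to_numpy()
    groups = [("male",), ("female",)] if by_sex else [("all",)]
    rows = []
    for amine in aminergic_sets:
        for (grp,) in groups:
            gmask = np.ones(adata.n_obs, dtype=bool) if grp == "all" else sex == grp
            base = amine_flags[amine].to_numpy() & gmask
            n = int(base.sum())
            row = {"aminergic_class": amine, "sex": grp, "n_cells": n}
            for fan in fan_sets:
                row[fan] = float((fan_flags[fan].to_numpy() & base).sum()) / n if n else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
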