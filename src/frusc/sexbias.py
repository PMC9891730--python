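"""Cluster sex-composition classification and sex-DE aggregation.

Because droplet captures rarely yield equal numbers of cells from each
sex, per-cluster female cell counts are divided by a global scaling
factor s (total female / total male cells in the filtered data) before
comparing.  A cluster is *sex-specific* when the other sex contributes
zero raw cells; otherwise the larger-to-smaller ratio of male vs
normalized female counts classifies it as sex-biased (> 2-fold), strongly
sex-biased (> 4-fold), or unbiased.  All inequalities are strict.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData

__all__ = [
    "scaling_factor",
    "compute_scaling",
    "classify_clusters",
    "summarize_sex_de",
    "class_tally",
]

CLASSES = [
    "male_specific",
    "female_specific",
    "male_biased_strong",
    "female_biased_strong",
    "male_biased",
    "female_biased",
    "unbiased",
]


def scaling_factor(n_female: int, n_male: int) -> float:
    """s = total female cells / total male cells."""
    if n_male <= 0:
        raise ValueError("cannot compute scaling factor with zero male cells")
    if n_female < 0:
        raise ValueError("female cell count must be non-negative")
    return n_female / n_male


def compute_scaling(adata: AnnData) -> float:
    """Female/male scaling factor from the (post-QC) matrix's sex labels."""
    sex = adata.obs["sex"]
    return scaling_factor(int((sex == "female").sum()), int((sex == "male").sum()))


def _classify_one(n_male: int, n_female_raw: int, s: float, fold_biased: float, fold_strong: float) -> tuple[str, float, float]:
    n_female_norm = n_female_raw / s
    if n_female_raw == 0 and n_male > 0:
        return "male_specific", np.inf, n_female_norm
    if n_male == 0 and n_female_raw > 0:
        return "female_specific", np.inf, n_female_norm
    hi, lo = max(n_male, n_female_norm), min(n_male, n_female_norm)
    ratio = hi / lo
    direction = "male" if n_male > n_female_norm else "female"
    if ratio > fold_strong:
        return f"{direction}_biased_strong", ratio, n_female_norm
    if ratio > fold_biased:
        return f"{direction}_biased", ratio, n_female_norm
    return "unbiased", ratio, n_female_norm


def classify_clusters(
    counts: pd.DataFrame | dict,
    s: float,
    fold_biased: float = 2.0,
    fold_strong: float = 4.0,
) -> pd.DataFrame:
    """Classify each cluster's sex composition.

    ``counts``: DataFrame indexed by cluster with columns ``n_male``,
    ``n_female`` (raw), or a mapping cluster -> (n_male, n_female).
    Specificity is judged on raw counts; bias direction and magnitude on
    the normalized female count ``n_female / s``.  Empty clusters are
    excluded with a warning.
    """
    if s <= 0:
        raise ValueError("scaling factor must be positive")
    if isinstance(counts, dict):
        counts = pd.DataFrame(
            {c: {"n_male": m, "n_female": f} for c, (m, f) in counts.items()}
        ).T
    rows = []
    for cluster, row in counts.iterrows():
        n_male, n_female = int(row["n_male"]), int(row["n_female"])
        if n_male < 0 or n_female < 0:
            raise ValueError(f"negative cell count for cluster {cluster}")
        if n_male == 0 and n_female == 0:
            warnings.warn(f"cluster {cluster} is empty; excluded from sex-bias report")
            continue
        cls, ratio, n_female_norm = _classify_one(n_male, n_female, s, fold_biased, fold_strong)
        rows.append(
            {
                "cluster": cluster,
                "n_male": n_male,
                "n_female_raw": n_female,
                "n_female_norm": n_female_norm,
                "ratio": ratio,
                "class": cls,
            }
        )
    report = pd.DataFrame(rows, columns=["cluster", "n_male", "n_female_raw", "n_female_norm", "ratio", "class"])
    report.attrs["scaling_factor"] = s
    return report


def sex_counts_per_cluster(labels: np.ndarray | pd.Series, sex: np.ndarray | pd.Series) -> pd.DataFrame:
    """Tabulate raw male/female cell counts per cluster."""
    df = pd.DataFrame({"cluster": np.asarray(labels), "sex": np.asarray(sex)})
    tab = df.groupby(["cluster", "sex"], observed=True).size().unstack(fill_value=0)
    out = pd.DataFrame(index=tab.index)
    out["n_male"] = tab.get("male", 0)
    out["n_female"] = tab.get("female", 0)
    return out


def summarize_sex_de(sex_de: pd.DataFrame) -> dict[str, set]:
    """Partition sex-DE genes into uniquely-male, uniquely-female, and
    mixed sets across clusters.  A gene is uniquely male-biased when it is
    male-biased in at least one cluster and female-biased in none."""
    if sex_de.empty:
        return {"uniquely_male": set(), "uniquely_female": set(), "mixed": set()}
    male = set(sex_de.loc[sex_de["direction"] == "male", "gene"])
    female = set(sex_de.loc[sex_de["direction"] == "female", "gene"])
    return {
        "uniquely_male": male - female,
        "uniquely_female": female - male,
        "mixed": male & female,
    }


def class_tally(report: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of clusters per sex-composition class."""
    n = len(report)
    tally = report["class"].value_counts().reindex(CLASSES, fill_value=0)
    return pd.DataFrame({"n_clusters": tally, "percent": 100.0 * tally / max(n, 1)})
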