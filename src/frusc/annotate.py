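"""Declarative marker-gene rules for cluster annotation, plus cell-level
gene-set classifiers.

The rule vocabulary follows the marker genes the fly field uses for these
populations: Hox genes place clusters in the ventral nerve cord; ey /
Dop1R2 with sNPF / Fas2 (and trio for the gamma subtype) identify
mushroom-body Kenyon cells; transporter / biosynthesis genes identify
fast-acting neurotransmitter (cholinergic, GABAergic, glutamatergic) and
aminergic (dopaminergic, serotonergic, tyraminergic/octopaminergic)
populations; a cluster with at least two core clock genes as markers is
annotated circadian.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "AnnotationRuleSet",
    "annotate_clusters",
    "classify_cells_by_sets",
    "select_serotonergic_vnc",
    "detection_fractions",
]


@dataclass
class AnnotationRuleSet:
    hox: list[str] = field(default_factory=lambda: ["Antp", "Ubx", "abd-A", "Abd-B"])
    kc_core: list[str] = field(default_factory=lambda: ["ey", "Dop1R2"])
    kc_axon: list[str] = field(default_factory=lambda: ["sNPF", "Fas2"])
    kc_gamma: list[str] = field(default_factory=lambda: ["trio"])
    cholinergic: list[str] = field(default_factory=lambda: ["VAChT", "ChAT"])
    gabaergic: list[str] = field(default_factory=lambda: ["Gad1", "VGAT"])
    glutamatergic: list[str] = field(default_factory=lambda: ["VGlut"])
    aminergic: list[str] = field(default_factory=lambda: ["Vmat"])
    dopaminergic: list[str] = field(default_factory=lambda: ["DAT", "ple"])
    serotonergic: list[str] = field(default_factory=lambda: ["SerT"])
    tyr_oct: list[str] = field(default_factory=lambda: ["Tdc2"])
    circadian: list[str] = field(default_factory=lambda: ["per", "tim", "Clk", "vri", "Pdp1"])
    neuropeptides: list[str] = field(default_factory=list)
    receptors: list[str] = field(default_factory=list)
    # detection-fraction cutoff for "expressed in the cluster but not a marker"
    expressed_fraction: float = 0.25

    def __post_init__(self) -> None:
        for name in ("hox", "kc_core", "kc_axon", "kc_gamma", "cholinergic",
                     "gabaergic", "glutamatergic", "aminergic", "dopaminergic",
                     "serotonergic", "tyr_oct", "circadian"):
            if not getattr(self, name):
                raise ValueError(f"rule gene list '{name}' must be non-empty")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnotationRuleSet":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def detection_fractions(adata: AnnData, labels: np.ndarray | pd.Series, genes: list[str] | None = None) -> pd.DataFrame:
    """Per-cluster fraction of cells with raw UMIs > 0, clusters x genes."""
    labels = np.asarray(labels)
    X = adata.layers.get("counts")
    X = sp.csr_matrix(X if X is not None else adata.X)
    if genes is not None:
        idx = [adata.var_names.get_loc(g) for g in genes if g in adata.var_names]
        X = X[:, idx]
        cols = [g for g in genes if g in adata.var_names]
    else:
        cols = list(adata.var_names)
    det = np.asarray((X > 0).todense())
    rows = {}
    for c in sorted(pd.unique(labels).tolist()):
        rows[c] = det[labels == c].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _hits(markers: set, genes: list[str]) -> list[str]:
    return [g for g in genes if g in markers]


def annotate_clusters(
    marker_table,
    rules: AnnotationRuleSet | None = None,
    expression_summary: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the boolean marker-gene rules per cluster.

    ``marker_table``: a :class:`~frusc.markers.MarkerTable` or a DataFrame
    with ``cluster``/``gene`` columns.  ``expression_summary``: clusters x
    genes detection fractions, needed only for the low-confidence KC rule
    ("expressed in the cluster but not a marker").  Returns a tidy frame
    (cluster, label, confidence, supporting_genes).
    """
    rules = rules or AnnotationRuleSet()
    df = marker_table.records if hasattr(marker_table, "records") else marker_table
    by_cluster = {c: set(g["gene"]) for c, g in df.groupby("cluster", observed=True)}
    if expression_summary is not None:
        for c in expression_summary.index:
            by_cluster.setdefault(c, set())

    rows = []

    def add(cluster, label, confidence, genes):
        rows.append(
            {"cluster": cluster, "label": label, "confidence": confidence,
             "supporting_genes": ",".join(genes)}
        )

    for cluster in sorted(by_cluster):
        markers = by_cluster[cluster]

        hox = _hits(markers, rules.hox)
        if hox:
            add(cluster, "VNC", "high", hox)

        core = _hits(markers, rules.kc_core)
        axon = _hits(markers, rules.kc_axon)
        gamma = _hits(markers, rules.kc_gamma)
        if core and axon:
            if gamma:
                add(cluster, "gamma_KC", "high", core + axon + gamma)
            else:
                add(cluster, "ab_KC", "high", core + axon)
        else:
            # lower-confidence KC calls (flagged "*" in reports)
            low = None
            if len(axon) == len(rules.kc_axon) and not core and expression_summary is not None and cluster in expression_summary.index:
                expressed_core = [
                    g for g in rules.kc_core
                    if g in expression_summary.columns
                    and expression_summary.loc[cluster, g] >= rules.expressed_fraction
                ]
                if expressed_core:
                    low = axon + expressed_core
            if low is None and gamma:
                other = _hits(markers, ["Fas2", "Dop1R2"])
                if len(other) == 1:
                    low = gamma + other
            if low is not None:
                add(cluster, "KC", "low", low)

        for label, genes in (
            ("cholinergic", rules.cholinergic),
            ("gabaergic", rules.gabaergic),
            ("glutamatergic", rules.glutamatergic),
        ):
            hit = _hits(markers, genes)
            if hit:
                add(cluster, label, "high", hit)

        for label, genes in (
            ("aminergic", rules.aminergic),
            ("dopaminergic", rules.dopaminergic),
            ("serotonergic", rules.serotonergic),
            ("tyr_oct", rules.tyr_oct),
        ):
            hit = _hits(markers, genes)
            if hit:
                add(cluster, label, "high", hit)

        circ = _hits(markers, rules.circadian)
        if len(circ) >= 2:
            add(cluster, "circadian", "high", circ)

        if rules.neuropeptides:
            hit = _hits(markers, rules.neuropeptides)
            if hit:
                add(cluster, "neuropeptide", "high", hit)
        if rules.receptors:
            hit = _hits(markers, rules.receptors)
            if hit:
                add(cluster, "receptor", "high", hit)

    return pd.DataFrame(rows, columns=["cluster", "label", "confidence", "supporting_genes"])


def classify_cells_by_sets(adata: AnnData, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Per-cell boolean flag per gene set: true when any member gene has
    raw UMIs > 0.  Unresolvable genes are warned about and skipped."""
    X = adata.layers.get("counts")
    X = sp.csr_matrix(X if X is not None else adata.X)
    out = {}
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in adata.var_names]
        missing = set(genes) - set(present)
        if missing:
            warnings.warn(f"gene set '{name}': unresolvable gene(s) {sorted(missing)}")
        if present:
            idx = [adata.var_names.get_loc(g) for g in present]
            out[name] = np.asarray((X[:, idx] > 0).sum(axis=1)).ravel() > 0
        else:
            out[name] = np.zeros(adata.n_obs, dtype=bool)
    return pd.DataFrame(out, index=adata.obs_names)


def select_serotonergic_vnc(
    adata: AnnData,
    sert_gene: str = "SerT",
    hox_genes: tuple[str, str] = ("abd-A", "Abd-B"),
) -> tuple[pd.Series, dict[str, int]]:
    """Cells expressing SerT together with abd-A and/or Abd-B — the
    putative serotonergic abdominal-ganglion population; returns the mask
    and per-sex counts."""
    flags = classify_cells_by_sets(adata, {"sert": [sert_gene], "hox": list(hox_genes)})
    mask = flags["sert"] & flags["hox"]
    sex = adata.obs["sex"]
    counts = {
        "male": int((mask & (sex == "male").to_numpy()).sum()),
        "female": int((mask & (sex == "female").to_numpy()).sum()),
    }
    return mask.rename("serotonergic_vnc"), counts
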