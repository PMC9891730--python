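"""End-to-end orchestration: QC -> normalization -> PC selection ->
clustering -> markers -> sex bias -> annotation -> co-expression ->
robustness, driven by one config, with every parameter recorded in a
manifest for reproducibility.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import coexpr as _coexpr
from . import embed as _embed
from . import markers as _markers
from . import qc as _qc
from . import robustness as _robustness
from . import sexbias as _sexbias

log = logging.getLogger("frusc")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run.  Input is a 10x-style triplet plus
    metadata TSV; every stochastic stage derives its seed from ``seed``."""

    matrix_path: str
    genes_path: str
    barcodes_path: str
    meta_path: str
    out_dir: str
    max_mito_fraction: float = 0.05
    min_genes: int = 200
    max_genes: int = 4000
    max_umis: int = 20000
    mito_prefix: str = "mt:"
    scale_factor: float = 1e4
    n_hvg: int = 2000
    max_pcs: int = 20
    jackstraw_reps: int = 100
    resolution: float = 1.0
    k_neighbors: int = 20
    min_pct: float = 0.25
    logfc_threshold: float = 0.25
    alpha: float = 0.05
    fold_biased: float = 2.0
    fold_strong: float = 4.0
    rules_path: str | None = None
    n_downsample_runs: int = 0
    run_umap: bool = False
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate(self) -> None:
        for name in ("matrix_path", "genes_path", "barcodes_path", "meta_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.rules_path is not None and not Path(self.rules_path).exists():
            raise FileNotFoundError(f"rules_path: {self.rules_path} does not exist")


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)


def run_all(config: PipelineConfig) -> Path:
    """Run every stage in order and write stage artifacts plus
    ``manifest.json`` to ``config.out_dir``.  Deterministic for a fixed
    config.  Raises at the failing stage; earlier artifacts remain."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_log: list[dict] = []

    def mark(stage: str, **info):
        stage_log.append({"stage": stage, "elapsed_s": round(time.time() - t0, 2), **info})
        log.info("stage %s done (%s)", stage, info)

    adata = _qc.load_counts(config.matrix_path, config.genes_path, config.barcodes_path, config.meta_path)
    thresholds = _qc.QCThresholds(
        max_mito_fraction=config.max_mito_fraction,
        min_genes=config.min_genes,
        max_genes=config.max_genes,
        max_umis=config.max_umis,
    )
    filtered, qc_report = _qc.filter_cells(adata, thresholds, mito_prefix=config.mito_prefix)
    _write_tsv(qc_report, out / "qc_report.tsv")
    neuron_flags, neuron_fraction = _qc.classify_neurons(filtered)
    mark("qc", cells_in=adata.n_obs, cells_kept=filtered.n_obs, neuron_fraction=round(neuron_fraction, 4))

    norm = _embed.log_normalize(filtered, scale_factor=config.scale_factor)
    hvgs = _embed.select_hvgs(norm, n=config.n_hvg)
    pca = _embed.jackstraw_select_pcs(
        norm, hvgs, max_pcs=config.max_pcs, n_reps=config.jackstraw_reps, seed=config.seed, min_pcs=2
    )
    assignment = _embed.cluster_snn(
        pca, k=config.k_neighbors, resolution=config.resolution, seed=config.seed
    )
    cluster_df = pd.DataFrame({"cluster": assignment.labels}, index=norm.obs_names)
    if config.run_umap:
        coords = _embed.umap_embed(pca, seed=config.seed)
        cluster_df["umap1"], cluster_df["umap2"] = coords[:, 0], coords[:, 1]
    _write_tsv(cluster_df, out / "clusters.tsv")
    mark("embed_cluster", n_pcs=pca.n_selected, n_clusters=assignment.n_clusters)

    marker_table = _markers.find_markers(
        norm, assignment.labels, min_pct=config.min_pct,
        logfc_threshold=config.logfc_threshold, alpha=config.alpha,
    )
    _write_tsv(marker_table.records, out / "markers.tsv", index=False)
    sex_de = _markers.find_sex_de_within_cluster(
        norm, assignment.labels, min_pct=config.min_pct,
        logfc_threshold=config.logfc_threshold, alpha=config.alpha,
    )
    _write_tsv(sex_de, out / "sex_de.tsv", index=False)
    mark("markers", n_markers=len(marker_table.records), n_sex_de=len(sex_de))

    s = _sexbias.compute_scaling(filtered)
    counts = _sexbias.sex_counts_per_cluster(assignment.labels, filtered.obs["sex"].to_numpy())
    bias_report = _sexbias.classify_clusters(
        counts, s, fold_biased=config.fold_biased, fold_strong=config.fold_strong
    )
    _write_tsv(bias_report, out / "sex_bias.tsv", index=False)
    de_summary = _sexbias.summarize_sex_de(sex_de)
    (out / "sex_de_summary.json").write_text(
        json.dumps({k: sorted(v) for k, v in de_summary.items()}, indent=2)
    )
    mark("sex_bias", scaling_factor=round(s, 4))

    rules = (
        _annotate.AnnotationRuleSet.from_json(config.rules_path)
        if config.rules_path
        else _annotate.AnnotationRuleSet()
    )
    rule_genes = sorted({g for lst in (rules.kc_core, rules.kc_axon) for g in lst})
    expr = _annotate.detection_fractions(norm, assignment.labels, genes=rule_genes)
    annotation = _annotate.annotate_clusters(marker_table, rules, expression_summary=expr)
    _write_tsv(annotation, out / "annotations.tsv", index=False)
    mark("annotate", n_labels=len(annotation))

    fan_sets = {"cholinergic": ["VAChT"], "gabaergic": ["Gad1"], "glutamatergic": ["VGlut"]}
    fan_present = {k: v for k, v in fan_sets.items() if v[0] in norm.var_names}
    if len(fan_present) == 3:
        overlaps = _coexpr.overlap_proportions(norm, ("VAChT", "Gad1", "VGlut"))
        (out / "fan_overlap.json").write_text(json.dumps(overlaps, indent=2))
    mark("coexpression")

    if config.n_downsample_runs > 0:
        ref_profiles = _robustness.cluster_profiles(norm, assignment.labels, hvgs)
        n_male = int((filtered.obs["sex"] == "male").sum())
        run_reports, run_matches = [], []
        for i in range(config.n_downsample_runs):
            run_seed = config.seed + 1000 + i
            sub = _robustness.downsample(filtered, {"female": min(n_male, int((filtered.obs["sex"] == "female").sum()))}, seed=run_seed)
            sub_norm = _embed.log_normalize(sub, scale_factor=config.scale_factor)
            sub_hvgs = _embed.select_hvgs(sub_norm, n=config.n_hvg)
            sub_pca = _embed.jackstraw_select_pcs(
                sub_norm, sub_hvgs, max_pcs=config.max_pcs,
                n_reps=config.jackstraw_reps, seed=run_seed, min_pcs=2,
            )
            sub_assign = _embed.cluster_snn(sub_pca, k=config.k_neighbors, resolution=config.resolution, seed=run_seed)
            q_profiles = _robustness.cluster_profiles(sub_norm, sub_assign.labels, hvgs)
            match = _robustness.match_clusters(ref_profiles, q_profiles)
            sub_s = _sexbias.compute_scaling(sub)
            sub_counts = _sexbias.sex_counts_per_cluster(sub_assign.labels, sub.obs["sex"].to_numpy())
            rep = _sexbias.classify_clusters(sub_counts, sub_s, config.fold_biased, config.fold_strong)
            run_reports.append(rep)
            run_matches.append(match)
            _write_tsv(match, out / f"downsample_match_run{i}.tsv", index=False)
        concordance = _robustness.concordance_report(bias_report, run_reports, run_matches)
        _write_tsv(concordance, out / "downsample_concordance.tsv", index=False)
        mark("robustness", n_runs=config.n_downsample_runs)

    manifest = {"config": asdict(config), "stages": stage_log, "versions": _versions()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _versions() -> dict[str, str]:
    import anndata, numpy, pandas, scipy, sklearn
    import frusc

    return {
        "frusc": frusc.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "anndata": anndata.__version__,
        "scikit-learn": sklearn.__version__,
    }
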