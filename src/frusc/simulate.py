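"""Synthetic count matrices and activity traces with planted ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: negative-binomial UMI counts with cluster-specific marker genes,
two sexes with (optionally unequal) cell totals, replicate structure,
mitochondrial genes, droplet artifacts (empty droplets, high-mitochondria
cells, multiplets), and per-fly minute-binned beam-cross activity with a
plantable circadian period and sleep blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "SimCountSpec",
    "SimActivitySpec",
    "ActivityTrace",
    "simulate_counts",
    "simulate_activity",
    "write_counts_10x",
    "write_activity_csv",
]

MITO_PREFIX = "mt:"


@dataclass
class SimCountSpec:
    """Parameters for a planted-structure UMI count matrix.

    ``cells_per_cluster_per_sex`` maps ``(cluster, sex)`` to a cell count;
    zeros plant sex-specific clusters.  When ``None``, every cluster gets
    ``default_cells_per_sex`` cells of each sex.
    """

    n_clusters: int = 5
    cells_per_cluster_per_sex: Mapping[tuple[int, str], int] | None = None
    default_cells_per_sex: int = 50
    n_genes: int = 1000
    baseline_mean: float = 0.5
    gene_mean_sigma: float = 1.0
    dispersion: float = 0.5
    markers_per_cluster: int = 40
    marker_fold: float = 4.0
    mito_gene_fraction: float = 0.01
    empty_rate: float = 0.02
    high_mito_rate: float = 0.02
    multiplet_rate: float = 0.02
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_clusters", "n_genes", "markers_per_cluster", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer, got {getattr(self, name)}")
        if self.gene_mean_sigma < 0:
            raise ValueError(f"gene_mean_sigma must be non-negative, got {self.gene_mean_sigma}")
        for name in ("baseline_mean", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.marker_fold <= 1:
            raise ValueError(f"marker_fold must exceed 1, got {self.marker_fold}")
        for name in ("mito_gene_fraction", "empty_rate", "high_mito_rate", "multiplet_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.n_clusters * self.markers_per_cluster > self.n_genes:
            raise ValueError("markers_per_cluster: marker sets must fit disjointly in n_genes")
        if self.cells_per_cluster_per_sex is not None:
            for (c, s), n in self.cells_per_cluster_per_sex.items():
                if n < 0:
                    raise ValueError(f"cells_per_cluster_per_sex[{(c, s)}] must be non-negative")
        elif self.default_cells_per_sex < 0:
            raise ValueError("default_cells_per_sex must be non-negative")

    def cell_table(self) -> dict[tuple[int, str], int]:
        if self.cells_per_cluster_per_sex is not None:
            return dict(self.cells_per_cluster_per_sex)
        return {
            (c, s): self.default_cells_per_sex
            for c in range(self.n_clusters)
            for s in ("male", "female")
        }


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion)
    return rng.poisson(lam)


def _expected_detected(means: np.ndarray, phi: float) -> float:
    # expected detected genes under NB zero probability (1 + phi*m)^(-1/phi)
    return float(np.sum(1.0 - (1.0 + phi * means) ** (-1.0 / phi)))


def _empty_droplet_scale(means: np.ndarray, phi: float, target_genes: float) -> float:
    """Mean multiplier making the expected detected-gene count equal
    target_genes (capped at half the baseline expectation), by bisection."""
    target = min(target_genes, 0.5 * _expected_detected(means, phi))
    lo, hi = 1e-6, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_detected(means * mid, phi) > target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def simulate_counts(spec: SimCountSpec) -> AnnData:
    """Generate a cells x genes UMI matrix with planted clusters and artifacts.

    Returns an :class:`~anndata.AnnData` with integer counts in ``X``,
    ground truth in ``obs`` (``sex``, ``replicate``, ``true_cluster``,
    ``artifact``) and ``var`` (``marker_for``), seed-reproducible.
    Non-marker genes draw lognormal per-gene base means (mean
    ``baseline_mean``, log-scale sigma ``gene_mean_sigma``) so that
    variable-gene selection faces a realistic mean-dispersion landscape;
    planted marker genes sit at ``baseline_mean`` exactly and have their
    NB mean multiplied by ``marker_fold`` inside their cluster.  High-mito
    artifacts have mitochondrial means inflated to an expected mito
    fraction of ~0.3; empty droplets are scaled to detect ~100 genes;
    multiplets are sums of two random clean cells.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_mito = int(round(spec.mito_gene_fraction * spec.n_genes))
    gene_ids = [f"{MITO_PREFIX}gene{i}" for i in range(n_mito)] + [
        f"gene{i}" for i in range(spec.n_genes - n_mito)
    ]
    is_mito = np.array([g.startswith(MITO_PREFIX) for g in gene_ids])

    # disjoint marker sets drawn from non-mito genes
    non_mito_idx = np.flatnonzero(~is_mito)
    if spec.n_clusters * spec.markers_per_cluster > non_mito_idx.size:
        raise ValueError("markers_per_cluster: not enough non-mitochondrial genes for disjoint marker sets")
    marker_pool = rng.permutation(non_mito_idx)
    marker_sets = {
        c: np.sort(marker_pool[c * spec.markers_per_cluster : (c + 1) * spec.markers_per_cluster])
        for c in range(spec.n_clusters)
    }

    if spec.gene_mean_sigma > 0:
        mu = np.log(spec.baseline_mean) - 0.5 * spec.gene_mean_sigma**2
        base = rng.lognormal(mu, spec.gene_mean_sigma, size=spec.n_genes)
    else:
        base = np.full(spec.n_genes, spec.baseline_mean)
    # markers and mito genes sit at the typical mean: markers so the planted
    # fold is exact, mito genes so healthy-cell mito fractions stay tight
    all_marker_idx = np.concatenate([marker_sets[c] for c in range(spec.n_clusters)])
    base[all_marker_idx] = spec.baseline_mean
    base[is_mito] = spec.baseline_mean
    table = spec.cell_table()

    rows, clusters, sexes = [], [], []
    for c in range(spec.n_clusters):
        mean_c = base.copy()
        mean_c[marker_sets[c]] *= spec.marker_fold
        for sex in ("male", "female"):
            n = table.get((c, sex), 0)
            if n == 0:
                continue
            rows.append(_nb_counts(rng, np.tile(mean_c, (n, 1)), spec.dispersion))
            clusters.extend([c] * n)
            sexes.extend([sex] * n)
    if not rows:
        raise ValueError("cells_per_cluster_per_sex: no cells requested")
    X = np.vstack(rows)
    n_clean = X.shape[0]
    artifact = ["none"] * n_clean

    n_empty = int(round(spec.empty_rate * n_clean))
    n_high_mito = int(round(spec.high_mito_rate * n_clean))
    n_multi = int(round(spec.multiplet_rate * n_clean))

    extra_rows, extra_meta = [], []
    if n_empty:
        scale = _empty_droplet_scale(base, spec.dispersion, target_genes=100.0)
        mean_e = base * scale
        extra_rows.append(_nb_counts(rng, np.tile(mean_e, (n_empty, 1)), spec.dispersion))
        extra_meta += [("empty", -1)] * n_empty
    if n_high_mito and n_mito:
        # inflate mito means so the expected mito fraction is ~0.3
        target = 0.3
        m_mito = base[is_mito].sum()
        m_rest = base[~is_mito].sum()
        f = target * m_rest / (m_mito * (1.0 - target))
        for _ in range(n_high_mito):
            c = int(rng.integers(spec.n_clusters))
            mean_h = base.copy()
            mean_h[marker_sets[c]] *= spec.marker_fold
            mean_h[is_mito] *= f
            extra_rows.append(_nb_counts(rng, mean_h[None, :], spec.dispersion))
            extra_meta.append(("high_mito", c))
    if n_multi:
        pairs = [rng.choice(n_clean, size=2, replace=False) for _ in range(n_multi)]
        extra_rows.append(np.array([X[i] + X[j] for i, j in pairs]))
        extra_meta += [("multiplet", -1)] * n_multi

    if extra_rows:
        X = np.vstack([X] + extra_rows)
        for kind, c in extra_meta:
            artifact.append(kind)
            clusters.append(c)
            sexes.append("male" if rng.random() < 0.5 else "female")

    n_cells = X.shape[0]
    obs = pd.DataFrame(
        {
            "sex": pd.Categorical(sexes, categories=["male", "female"]),
            "replicate": [f"rep{int(rng.integers(spec.n_replicates)) + 1}" for _ in range(n_cells)],
            "true_cluster": clusters,
            "artifact": pd.Categorical(artifact, categories=["none", "empty", "high_mito", "multiplet"]),
        },
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    marker_for = np.full(spec.n_genes, -1)
    for c, idx in marker_sets.items():
        marker_for[idx] = c
    var = pd.DataFrame({"marker_for": marker_for, "is_mito": is_mito}, index=gene_ids)

    adata = AnnData(X=sp.csr_matrix(X.astype(np.int64)), obs=obs, var=var)
    adata.uns["sim_spec"] = {k: v for k, v in vars(spec).items() if k != "cells_per_cluster_per_sex"}
    return adata


@dataclass
class ActivityTrace:
    """Per-fly 1-minute binned beam-cross counts with a light schedule."""

    fly_id: str
    counts: np.ndarray
    lights_on: int = 480  # minute of day
    lights_off: int = 1200
    genotype: str = "unknown"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size % 1440:
            raise ValueError("trace length must be a positive multiple of 1440 minutes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_days(self) -> int:
        return self.counts.size // 1440


@dataclass
class SimActivitySpec:
    n_flies: int = 16
    n_days: int = 10
    period_h: float = 24.0
    amplitude: float = 1.0  # relative modulation depth of the Poisson rate
    baseline_rate: float = 1.0  # beam crossings per minute
    dead_fly_fraction: float = 0.0
    sleep_block_minutes: int = 0
    waveform: str = "sin"  # or "square"
    lights_on: int = 480
    lights_off: int = 1200
    seed: int = 0

    def validate(self) -> None:
        if self.n_flies < 1:
            raise ValueError(f"n_flies must be positive, got {self.n_flies}")
        if self.n_days < 1:
            raise ValueError(f"n_days must be positive, got {self.n_days}")
        if not 18.0 <= self.period_h <= 30.0:
            raise ValueError(f"period_h must lie in [18, 30], got {self.period_h}")
        if self.amplitude < 0 or self.baseline_rate < 0:
            raise ValueError("amplitude and baseline_rate must be non-negative")
        if not 0 <= self.dead_fly_fraction <= 1:
            raise ValueError(f"dead_fly_fraction must be in [0, 1], got {self.dead_fly_fraction}")
        if self.sleep_block_minutes < 0:
            raise ValueError("sleep_block_minutes must be non-negative")
        if self.waveform not in ("sin", "square"):
            raise ValueError(f"waveform must be 'sin' or 'square', got {self.waveform}")


def simulate_activity(spec: SimActivitySpec) -> list[ActivityTrace]:
    """Generate per-fly activity traces with a planted circadian period.

    The first ``round(dead_fly_fraction * n_flies)`` flies are "dead":
    they emit essentially no counts, so every full day falls below the
    50 counts/day liveness threshold used downstream.  Rhythmic flies are
    Poisson with rate ``baseline_rate * (1 + amplitude * w(t))`` where
    ``w`` is a sinusoid or square wave at ``period_h``; a nightly block of
    ``sleep_block_minutes`` zeros plants consolidated sleep.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_min = spec.n_days * 1440
    t = np.arange(n_min, dtype=float)
    phase = 2.0 * np.pi * t / (spec.period_h * 60.0)
    if spec.waveform == "sin":
        w = np.sin(phase)
    else:
        w = np.where(np.sin(phase) >= 0, 1.0, -1.0)
    rate = np.clip(spec.baseline_rate * (1.0 + spec.amplitude * w), 0.0, None)

    n_dead = int(round(spec.dead_fly_fraction * spec.n_flies))
    traces = []
    for i in range(spec.n_flies):
        if i < n_dead:
            counts = rng.poisson(0.005, size=n_min)
        else:
            counts = rng.poisson(rate)
            if spec.sleep_block_minutes:
                for day in range(spec.n_days):
                    start = day * 1440 + spec.lights_off % 1440
                    counts[start : start + spec.sleep_block_minutes] = 0
        traces.append(
            ActivityTrace(
                fly_id=f"fly{i:03d}",
                counts=counts,
                lights_on=spec.lights_on,
                lights_off=spec.lights_off,
            )
        )
    return traces


def write_counts_10x(adata: AnnData, outdir: str | Path) -> None:
    """Write a 10x-style triplet (matrix.mtx genes x cells, genes.tsv,
    barcodes.tsv) plus a cell metadata TSV (barcode, sex, replicate)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.astype(np.int64))
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = adata.obs.reset_index().rename(columns={"index": "barcode"})
    meta[["barcode", "sex", "replicate"]].to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)


def write_activity_csv(traces: Sequence[ActivityTrace], csv_path: str | Path, schedule_path: str | Path | None = None) -> None:
    """Write traces as long-form CSV (fly_id, minute_index, counts) plus a
    schedule JSON (lights_on, lights_off as minutes of day)."""
    frames = [
        pd.DataFrame({"fly_id": tr.fly_id, "minute_index": np.arange(tr.counts.size), "counts": tr.counts})
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    if schedule_path is not None and traces:
        Path(schedule_path).write_text(
            json.dumps({"lights_on": traces[0].lights_on, "lights_off": traces[0].lights_off})
        )
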