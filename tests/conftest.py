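import numpy as np
import pytest
import scipy.sparse as sp
from anndata import AnnData

from frusc.embed import jackstraw_select_pcs, log_normalize, select_hvgs, cluster_snn
from frusc.qc import filter_cells
from frusc.simulate import SimCountSpec, simulate_counts


def make_adata(X, gene_names=None, sex=None, replicate=None):
    """Small AnnData from a dense cells x genes count array."""
    X = np.asarray(X)
    n_obs, n_var = X.shape
    ad = AnnData(X=sp.csr_matrix(X.astype(np.int64)))
    ad.obs_names = [f"c{i}" for i in range(n_obs)]
    ad.var_names = gene_names if gene_names is not None else [f"g{i}" for i in range(n_var)]
    ad.obs["sex"] = sex if sex is not None else ["male"] * n_obs
    ad.obs["replicate"] = replicate if replicate is not None else ["rep1"] * n_obs
    return ad


@pytest.fixture(scope="session")
def sim_adata():
    """Planted 3-cluster matrix with artifacts, default study conditions."""
    return simulate_counts(SimCountSpec(n_clusters=3, default_cells_per_sex=50, seed=11))


@pytest.fixture(scope="session")
def pipeline_state(sim_adata):
    """QC -> normalize -> HVG -> jackstraw PCA -> SNN clusters, shared by
    the marker / sex-bias / robustness tests."""
    kept, report = filter_cells(sim_adata)
    norm = log_normalize(kept)
    hvgs = select_hvgs(norm, 300)
    pca = jackstraw_select_pcs(norm, hvgs, max_pcs=10, seed=11, min_pcs=2)
    assignment = cluster_snn(pca, resolution=0.5, seed=11)
    return {
        "raw": sim_adata,
        "kept": kept,
        "qc_report": report,
        "norm": norm,
        "hvgs": hvgs,
        "pca": pca,
        "assignment": assignment,
    }
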