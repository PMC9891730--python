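from itertools import combinations

import numpy as np
import pytest
from scipy.stats import norm as normal_dist
from scipy.stats import rankdata

from conftest import make_adata
from frusc.embed import log_normalize
from frusc.markers import (
    MarkerTable,
    find_markers,
    find_sex_de_within_cluster,
    log_fold_change,
    ranksum_p,
    top_markers,
)


def exact_ranksum_p(x, y):
    """Independent oracle: enumerate all rank assignments (no ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in combinations(range(n1 + n2), n1):
        r = np.sort(rankdata(np.arange(n1 + n2)))[list(comb)]
        us.append(r.sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


def normal_tie_p(x, y):
    """Independent oracle: normal approximation with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    N = n1 + n2
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
    sigma = np.sqrt(n1 * n2 / 12 * ((N + 1) - tie_term))
    z = (u - n1 * n2 / 2) / sigma
    return 2 * normal_dist.sf(abs(z))


class TestRanksumOracle:
    def test_spec_example_enumeration(self):
        # {3,4} vs {1,2}: all 6 rank arrangements -> two-sided p = 1/3
        assert ranksum_p([3, 4], [1, 2]) == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n1, n2 = rng.integers(2, 9, size=2)
            x = rng.permutation(np.arange(n1 + n2, dtype=float))[:n1]
            y = np.setdiff1d(np.arange(n1 + n2, dtype=float), x)
            assert ranksum_p(x, y) == pytest.approx(exact_ranksum_p(x, y), abs=1e-10)

    def test_matches_tie_corrected_normal_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x = rng.integers(0, 4, size=rng.integers(10, 30)).astype(float)
            y = rng.integers(0, 4, size=rng.integers(10, 30)).astype(float)
            assert ranksum_p(x, y) == pytest.approx(normal_tie_p(x, y), abs=1e-10)


class TestLogFoldChange:
    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.exponential(1, 20), rng.exponential(2, 20)
        assert log_fold_change(a, b) == pytest.approx(-log_fold_change(b, a), abs=1e-12)

    def test_identical_distribution_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert log_fold_change(a, a) == 0.0


class TestFindMarkers:
    def test_identically_distributed_gene_not_marker(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(2.0, size=(60, 5))
        labels = np.array([0] * 30 + [1] * 30)
        norm = log_normalize(make_adata(X))
        table = find_markers(norm, labels)
        # no gene differs between groups; nothing should survive the fold filter
        assert len(table.records) == 0 or (table.records["log_fc"] >= 0.25).all()

    def test_planted_markers_detected(self, pipeline_state):
        norm = pipeline_state["norm"]
        truth = pipeline_state["kept"].obs["true_cluster"].to_numpy()
        table = find_markers(norm, truth)
        found = table.genes_by_cluster
        for c in range(3):
            planted = set(norm.var_names[norm.var["marker_for"] == c])
            assert len(planted & found.get(c, set())) >= 0.9 * len(planted)

    def test_small_cluster_skipped_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(2.0, size=(33, 10))
        labels = np.array([0] * 30 + [1] * 2 + [2] * 1)
        norm = log_normalize(make_adata(X))
        with pytest.warns(UserWarning, match="fewer than 3"):
            find_markers(norm, labels)

    def test_bonferroni_invariant(self, pipeline_state):
        norm = pipeline_state["norm"]
        truth = pipeline_state["kept"].obs["true_cluster"].to_numpy()
        rec = find_markers(norm, truth).records
        expected = np.minimum(1.0, rec["p_raw"] * norm.n_vars)
        assert np.allclose(rec["p_bonf"], expected)
        assert ((rec[["pct_in", "pct_out"]].max(axis=1)) >= 0.25).all()
        assert (rec["log_fc"] >= 0.25).all()

    def test_permutation_null_type_I_control(self, pipeline_state):
        norm = pipeline_state["norm"]
        rng = np.random.default_rng(5)
        labels = rng.permutation(pipeline_state["kept"].obs["true_cluster"].to_numpy())
        table = find_markers(norm, labels, p_filter="bonferroni")
        frac = table.records["gene"].nunique() / norm.n_vars
        assert frac <= 0.05


class TestSexDE:
    def test_all_or_nothing_gene_called(self):
        rng = np.random.default_rng(6)
        X = rng.poisson(1.0, size=(40, 6))
        X[:20, 0] = 10  # males high, females zero for gene 0
        X[20:, 0] = 0
        sex = ["male"] * 20 + ["female"] * 20
        norm = log_normalize(make_adata(X, sex=sex))
        df = find_sex_de_within_cluster(norm, np.zeros(40, dtype=int))
        hit = df[(df["gene"] == "g0") & (df["direction"] == "male")]
        assert len(hit) == 1

    def test_identical_sexes_no_calls(self):
        rng = np.random.default_rng(7)
        X = np.tile(rng.poisson(2.0, size=(20, 6)), (2, 1))
        sex = ["male"] * 20 + ["female"] * 20
        norm = log_normalize(make_adata(X, sex=sex))
        df = find_sex_de_within_cluster(norm, np.zeros(40, dtype=int))
        assert df.empty

    def test_single_sex_cluster_skipped(self):
        rng = np.random.default_rng(8)
        X = rng.poisson(2.0, size=(20, 4))
        norm = log_normalize(make_adata(X, sex=["male"] * 20))
        df = find_sex_de_within_cluster(norm, np.zeros(20, dtype=int))
        assert df.empty
        assert 0 in df.attrs["skipped"]


class TestTopMarkers:
    @staticmethod
    def _table(rows):
        import pandas as pd

        df = pd.DataFrame(rows)
        return MarkerTable(df, min_pct=0.25, logfc_threshold=0.25, alpha=0.05)

    def test_fewer_than_n_returns_all(self):
        t = self._table(
            [{"cluster": 0, "gene": g, "p_raw": 0.01, "p_bonf": 0.1, "log_fc": fc, "pct_in": 1, "pct_out": 0}
             for g, fc in [("a", 1.0), ("b", 0.5), ("c", 0.3)]]
        )
        assert len(top_markers(t, n=5)) == 3

    def test_tie_broken_by_p_then_gene(self):
        t = self._table(
            [{"cluster": 0, "gene": "x", "p_raw": 0.04, "p_bonf": 1, "log_fc": 1.0, "pct_in": 1, "pct_out": 0},
             {"cluster": 0, "gene": "y", "p_raw": 0.01, "p_bonf": 1, "log_fc": 1.0, "pct_in": 1, "pct_out": 0}]
        )
        assert top_markers(t, n=1)["gene"].iloc[0] == "y"

    def test_n1_returns_max_logfc(self):
        t = self._table(
            [{"cluster": 0, "gene": "lo", "p_raw": 0.001, "p_bonf": 1, "log_fc": 0.5, "pct_in": 1, "pct_out": 0},
             {"cluster": 0, "gene": "hi", "p_raw": 0.02, "p_bonf": 1, "log_fc": 2.0, "pct_in": 1, "pct_out": 0}]
        )
        assert top_markers(t, n=1)["gene"].iloc[0] == "hi"
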