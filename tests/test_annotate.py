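import numpy as np
import pandas as pd
import pytest

from conftest import make_adata
from frusc.annotate import (
    AnnotationRuleSet,
    annotate_clusters,
    classify_cells_by_sets,
    detection_fractions,
    select_serotonergic_vnc,
)

RULE_GENES = [
    "Antp", "Ubx", "abd-A", "Abd-B", "ey", "Dop1R2", "sNPF", "Fas2", "trio",
    "VAChT", "ChAT", "VGlut", "Gad1", "VGAT", "Vmat", "DAT", "ple", "SerT",
    "Tdc2", "per", "tim", "Clk", "vri", "Pdp1",
]


def table_from(markers_by_cluster):
    rows = [
        {"cluster": c, "gene": g, "p_raw": 0.01, "p_bonf": 0.1, "log_fc": 1.0, "pct_in": 0.8, "pct_out": 0.1}
        for c, genes in markers_by_cluster.items()
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["cluster", "gene", "p_raw", "p_bonf", "log_fc", "pct_in", "pct_out"])


def labels_of(ann, cluster):
    return set(ann.loc[ann["cluster"] == cluster, "label"])


class TestRuleExamples:
    def test_hox_markers_give_vnc(self):
        ann = annotate_clusters(table_from({0: ["Antp", "Ubx"], 1: ["other"]}))
        assert "VNC" in labels_of(ann, 0)
        assert "VNC" not in labels_of(ann, 1)

    def test_gamma_kc_high_confidence(self):
        ann = annotate_clusters(table_from({0: ["ey", "sNPF", "trio"]}))
        sub = ann[(ann["cluster"] == 0) & (ann["label"] == "gamma_KC")]
        assert len(sub) == 1 and sub["confidence"].iloc[0] == "high"

    def test_ab_kc_requires_absent_trio(self):
        ann = annotate_clusters(table_from({0: ["Dop1R2", "Fas2"]}))
        assert "ab_KC" in labels_of(ann, 0)
        assert "gamma_KC" not in labels_of(ann, 0)

    def test_kc_subtypes_mutually_exclusive(self):
        rng = np.random.default_rng(0)
        pool = ["ey", "Dop1R2", "sNPF", "Fas2", "trio", "x", "y"]
        for _ in range(100):
            genes = [g for g in pool if rng.random() < 0.5]
            ann = annotate_clusters(table_from({0: genes}))
            ls = labels_of(ann, 0)
            assert not ({"ab_KC", "gamma_KC"} <= ls)

    def test_two_clock_genes_give_circadian(self):
        ann = annotate_clusters(table_from({0: ["per", "tim"], 1: ["per"]}))
        assert "circadian" in labels_of(ann, 0)
        assert "circadian" not in labels_of(ann, 1)

    def test_fan_multilabel_allowed(self):
        ann = annotate_clusters(table_from({0: ["VAChT", "VGlut"]}))
        assert {"cholinergic", "glutamatergic"} <= labels_of(ann, 0)

    def test_low_confidence_kc_needs_expression_summary(self):
        t = table_from({0: ["sNPF", "Fas2"]})
        expr = pd.DataFrame({"ey": [0.6], "Dop1R2": [0.1]}, index=[0])
        ann = annotate_clusters(t, expression_summary=expr)
        sub = ann[(ann["cluster"] == 0) & (ann["label"] == "KC")]
        assert len(sub) == 1 and sub["confidence"].iloc[0] == "low"
        assert "ey" in sub["supporting_genes"].iloc[0]

    def test_trio_plus_one_other_kc_gene_low_confidence(self):
        ann = annotate_clusters(table_from({0: ["trio", "Dop1R2"]}))
        sub = ann[(ann["cluster"] == 0) & (ann["label"] == "KC")]
        assert len(sub) == 1 and sub["confidence"].iloc[0] == "low"

    def test_adding_unrelated_cluster_does_not_change_labels(self):
        base = table_from({0: ["Antp", "VAChT"]})
        more = table_from({0: ["Antp", "VAChT"], 1: ["SerT", "per", "tim"]})
        a = annotate_clusters(base)
        b = annotate_clusters(more)
        assert labels_of(a, 0) == labels_of(b, 0)


def naive_labels(markers: set, expressed: dict[str, float]) -> set:
    """Independent re-evaluation of the boolean rules, written plainly."""
    out = set()
    if markers & {"Antp", "Ubx", "abd-A", "Abd-B"}:
        out.add("VNC")
    core = markers & {"ey", "Dop1R2"}
    axon = markers & {"sNPF", "Fas2"}
    if core and axon:
        out.add("gamma_KC" if "trio" in markers else "ab_KC")
    else:
        low = False
        if axon == {"sNPF", "Fas2"} and not core:
            if any(expressed.get(g, 0) >= 0.25 for g in ("ey", "Dop1R2")):
                low = True
        if not low and "trio" in markers and len(markers & {"Fas2", "Dop1R2"}) == 1:
            low = True
        if low:
            out.add("KC")
    if markers & {"VAChT", "ChAT"}:
        out.add("cholinergic")
    if markers & {"Gad1", "VGAT"}:
        out.add("gabaergic")
    if "VGlut" in markers:
        out.add("glutamatergic")
    if "Vmat" in markers:
        out.add("aminergic")
    if markers & {"DAT", "ple"}:
        out.add("dopaminergic")
    if "SerT" in markers:
        out.add("serotonergic")
    if "Tdc2" in markers:
        out.add("tyr_oct")
    if len(markers & {"per", "tim", "Clk", "vri", "Pdp1"}) >= 2:
        out.add("circadian")
    return out


class TestBruteForceOracle:
    def test_random_marker_tables_match_naive_rules(self):
        rng = np.random.default_rng(1)
        for trial in range(300):
            markers = {g for g in RULE_GENES if rng.random() < 0.25}
            expressed = {g: float(rng.random()) for g in ("ey", "Dop1R2")}
            t = table_from({0: sorted(markers)})
            expr = pd.DataFrame(expressed, index=[0])
            ann = annotate_clusters(t, expression_summary=expr)
            assert labels_of(ann, 0) == naive_labels(markers, expressed), (
                f"trial {trial}: markers={sorted(markers)} expressed={expressed}"
            )


class TestCellLevelClassifiers:
    def test_set_flags(self):
        X = np.array([[2, 0, 0], [1, 0, 3], [0, 0, 0]])
        ad = make_adata(X, gene_names=["VAChT", "Gad1", "VGlut"])
        flags = classify_cells_by_sets(ad, {"chol": ["VAChT"], "gaba": ["Gad1"], "glut": ["VGlut"]})
        assert flags["chol"].tolist() == [True, True, False]
        assert flags["gaba"].tolist() == [False, False, False]
        assert flags["glut"].tolist() == [False, True, False]

    def test_unknown_gene_warns(self):
        ad = make_adata([[1]], gene_names=["VAChT"])
        with pytest.warns(UserWarning, match="unresolvable"):
            flags = classify_cells_by_sets(ad, {"chol": ["VAChT", "nope"]})
        assert flags["chol"].iloc[0]

    def test_serotonergic_vnc_counts(self):
        # 3 qualifying male + 2 qualifying female cells, 2 non-qualifying
        genes = ["SerT", "abd-A", "Abd-B"]
        X = np.array(
            [[1, 1, 0], [1, 0, 2], [2, 1, 1],   # qualifying males
             [1, 0, 1], [1, 3, 0],              # qualifying females
             [1, 0, 0],                          # SerT only
             [0, 1, 1]]                          # Hox only
        )
        sex = ["male"] * 3 + ["female"] * 2 + ["male", "female"]
        ad = make_adata(X, gene_names=genes, sex=sex)
        mask, counts = select_serotonergic_vnc(ad)
        assert counts == {"male": 3, "female": 2}
        assert mask.sum() == 5

    def test_detection_fractions(self):
        X = np.array([[1, 0], [1, 0], [0, 2], [0, 0]])
        ad = make_adata(X, gene_names=["a", "b"])
        labels = np.array([0, 0, 1, 1])
        frac = detection_fractions(ad, labels)
        assert frac.loc[0, "a"] == 1.0
        assert frac.loc[1, "b"] == 0.5


class TestRuleSetConfig:
    def test_json_roundtrip(self, tmp_path):
        rules = AnnotationRuleSet(neuropeptides=["CCHa2", "AstC"])
        rules.to_json(tmp_path / "rules.json")
        back = AnnotationRuleSet.from_json(tmp_path / "rules.json")
        assert back.neuropeptides == ["CCHa2", "AstC"]
        assert back.hox == rules.hox

    def test_empty_core_list_rejected(self):
        with pytest.raises(ValueError, match="hox"):
            AnnotationRuleSet(hox=[])

    def test_neuropeptide_flag(self):
        rules = AnnotationRuleSet(neuropeptides=["CCHa2"])
        ann = annotate_clusters(table_from({0: ["CCHa2"]}), rules)
        assert "neuropeptide" in labels_of(ann, 0)
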