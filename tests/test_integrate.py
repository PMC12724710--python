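"""Feature selection, heatmap blocks and serum-response categorisation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import matrix_from
from glycophos.integrate import (IntegrationConfig, build_block,
                                 categorize_response, collapse_to_proteins,
                                 cut_samples, pathway_heatmap, phospho_gene,
                                 select_features)


def _f_table(n, fdr=0.01, f_values=None, ids=None):
    ids = ids or [f"f{i:04d}" for i in range(n)]
    f_values = f_values if f_values is not None else np.arange(n, dtype=float)
    return pd.DataFrame({"F": f_values, "fdr": fdr},
                        index=pd.Index(ids, name="feature_id"))


def test_select_features_truncates_to_largest_F():
    table = _f_table(600)
    cfg = IntegrationConfig(top_k=500)
    out = select_features(table, cfg)
    assert len(out) == 500
    expected = set(table.sort_values("F", ascending=False).index[:500])
    assert set(out) == expected


def test_select_features_returns_all_passing_when_few():
    table = _f_table(10, fdr=[0.01] * 3 + [0.5] * 7)
    out = select_features(table, IntegrationConfig(top_k=500))
    assert len(out) == 3


def test_select_features_tie_break_and_order_invariance():
    table = _f_table(6, f_values=[5.0, 5.0, 5.0, 1.0, 9.0, 5.0])
    cfg = IntegrationConfig(top_k=3)
    out = select_features(table, cfg)
    assert out == ["f0004", "f0000", "f0001"]   # top F, then id order among ties
    shuffled = table.sample(frac=1, random_state=0)
    assert select_features(shuffled, cfg) == out


def test_build_block_zscore_and_constant_row_dropped():
    vals = np.vstack([np.arange(6.0), np.full(6, 3.0), np.arange(6.0)[::-1],
                      np.arange(6.0) * 2])
    m = matrix_from(vals)
    block = build_block(m, list(m.feature_ids), IntegrationConfig(completeness=0.5))
    assert "f1" in block.dropped_rows
    z = block.values
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
    assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)


def test_build_block_completeness_filter_uses_detection_mask():
    vals = np.arange(24.0).reshape(4, 6)
    m = matrix_from(vals)
    m.detected.iloc[0, :4] = False     # f0 detected in 2/6 < 70%
    block = build_block(m, list(m.feature_ids), IntegrationConfig())
    assert "f0" not in block.values.index


def test_complete_linkage_hand_agglomeration():
    """One-dimensional samples at 0, 1, 10: (0,1) merge first, then 10."""
    vals = np.array([[0.0, 1.0, 10.0], [0.0, 1.0, 10.0], [0.1, 1.1, 9.9]])
    m = matrix_from(vals)
    block = build_block(m, list(m.feature_ids),
                        IntegrationConfig(completeness=0.5))
    Z = block.col_linkage
    # first merge joins leaves 0 and 1; the final merge height reflects s2
    assert set(Z[0, :2].astype(int)) == {0, 1}
    order = block.col_order
    assert order.index("s2") in (0, 2)   # outlier sits at one end


def test_build_block_too_small_raises():
    m = matrix_from(np.ones((1, 6)))
    with pytest.raises(ValueError):
        build_block(m, ["f0"], IntegrationConfig(completeness=0.5))


# ----------------------------------------------------------------------
# response categorisation
# ----------------------------------------------------------------------

def _de(ids, sig):
    return pd.DataFrame({"significant": sig},
                        index=pd.Index(ids, name="feature_id"))


def test_categorize_response_partition():
    ids = ["A_S1", "B_S2", "C_S3", "D_S4"]
    wt = _de(ids, [True, True, False, False])
    ai = _de(["A_S1", "B_S2", "C_S3", "E_S5"], [True, False, True, True])
    cat = categorize_response(wt, ai)
    assert len(cat) == 5                       # union universe
    assert cat.loc["A_S1", "category"] == "Both"
    assert cat.loc["B_S2", "category"] == "WT*"
    assert cat.loc["C_S3", "category"] == "AI*"
    assert cat.loc["D_S4", "category"] == "NS"
    assert cat.loc["E_S5", "category"] == "AI*"
    counts = cat["category"].value_counts()
    assert counts.sum() == len(cat)


def test_categorize_response_counts_reflect_blunting(small_dataset):
    from glycophos.containers import design_subset
    from glycophos.modstats import pairwise_de
    from glycophos.preprocess import preprocess_layer
    res = preprocess_layer(small_dataset["matrices"]["phospho"],
                           small_dataset["design"], seed=5)
    design = small_dataset["design"]
    wt = pairwise_de(res["imputed"], design_subset(design, cell_line="WT"),
                     "condition", "treated", "untreated")
    ai = pairwise_de(res["imputed"], design_subset(design, cell_line="AI"),
                     "condition", "treated", "untreated")
    cat = categorize_response(wt, ai)
    counts = cat["category"].value_counts()
    assert counts.get("WT*", 0) > counts.get("AI*", 0)


def test_phospho_gene_grammar():
    assert phospho_gene("EGFR_T711") == "EGFR"
    assert phospho_gene("RPS6KB2_S443") == "RPS6KB2"
    assert phospho_gene("NUP_153_S43") == "NUP_153"   # underscores in gene names
    for bad in ("EGFR", "EGFR_Q711", "EGFR_S", "EGFR_711"):
        with pytest.raises(ValueError):
            phospho_gene(bad)


def test_collapse_to_proteins_rules_and_bruteforce():
    sites = {
        "P1_S1": (True, False), "P1_S2": (False, True),   # WT*+AI* -> Both
        "P2_S1": (False, False),                           # NS
        "P3_S1": (True, True),                             # Both
        "P4_S1": (True, False), "P4_S2": (True, False),    # WT*
        "P5_S1": (False, True), "P5_S2": (False, False),   # AI*
    }
    wt = _de(list(sites), [v[0] for v in sites.values()])
    ai = _de(list(sites), [v[1] for v in sites.values()])
    cat = categorize_response(wt, ai)
    prot = collapse_to_proteins(cat)
    assert prot.loc["P1", "category"] == "Both"
    assert prot.loc["P2", "category"] == "NS"
    assert prot.loc["P3", "category"] == "Both"
    assert prot.loc["P4", "category"] == "WT*"
    assert prot.loc["P5", "category"] == "AI*"
    # brute-force re-derivation of counts
    expect = {}
    for site, (w, a) in sites.items():
        g = site.split("_")[0]
        prev = expect.get(g, (False, False))
        expect[g] = (prev[0] or w, prev[1] or a)
    for g, (w, a) in expect.items():
        want = "Both" if w and a else "WT*" if w else "AI*" if a else "NS"
        assert prot.loc[g, "category"] == want


def test_collapse_skips_malformed_ids():
    cat = categorize_response(_de(["GOOD_S1", "bad-id"], [True, True]),
                              _de(["GOOD_S1", "bad-id"], [False, False]))
    prot = collapse_to_proteins(cat)
    assert list(prot.index) == ["GOOD"]
    assert prot.attrs["skipped_sites"] == ["bad-id"]


# ----------------------------------------------------------------------
# pathway heatmap
# ----------------------------------------------------------------------

def test_pathway_heatmap_groups_and_within_group_order():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(8, 6))
    ids = [f"G{i}_S{i}" for i in range(8)]
    m = matrix_from(vals, feature_ids=ids, layer="phospho")
    pathways = {"pwB": ids[:4], "pwA": ids[4:]}
    block = pathway_heatmap(m, pathways, IntegrationConfig(completeness=0.5))
    # supervised grouping: pathways in sorted label order, no interleaving
    assert block.row_order[:4] == block.row_groups["pwA"]
    assert block.row_order[4:] == block.row_groups["pwB"]
    # within-group leaf order equals standalone clustering of that group
    sub = build_block(m, ids[4:], IntegrationConfig(completeness=0.5))
    assert block.row_groups["pwA"] == sub.row_order


def test_pathway_heatmap_single_pathway_reduces_to_block():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=(5, 6))
    ids = [f"G{i}_S{i}" for i in range(5)]
    m = matrix_from(vals, feature_ids=ids, layer="phospho")
    block = pathway_heatmap(m, {"only": ids}, IntegrationConfig(completeness=0.5))
    plain = build_block(m, ids, IntegrationConfig(completeness=0.5))
    assert block.row_order == plain.row_order


def test_pathway_with_single_site_left_unclustered():
    vals = np.arange(18.0).reshape(3, 6)
    ids = ["A_S1", "B_S2", "C_S3"]
    m = matrix_from(vals, feature_ids=ids, layer="phospho")
    block = pathway_heatmap(m, {"solo": ["A_S1"], "pair": ["B_S2", "C_S3"]},
                            IntegrationConfig(completeness=0.5))
    assert block.row_groups["solo"] == ["A_S1"]


def test_cut_samples_labels(small_dataset):
    from glycophos.modstats import factorial_F
    from glycophos.preprocess import preprocess_layer
    res = preprocess_layer(small_dataset["matrices"]["glyco"],
                           small_dataset["design"], seed=5)
    ff = factorial_F(res["imputed"], small_dataset["design"])
    feats = select_features(ff, IntegrationConfig())
    block = build_block(res["imputed"], feats)
    cut = cut_samples(block, 2)
    assert set(cut.unique()) == {1, 2}
    assert len(cut) == 12
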