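"""TO-GCN construction: expression filter, DE gate, signed network, seed
selection, level assignment and stage mapping."""

import numpy as np
import pytest

import azaleanet as az

from .conftest import make_matrix


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def test_filter_threshold_boundary():
    m = make_matrix({"low": [0.4] * 5, "kept": [0.6] * 5, "edge": [0.5] * 5})
    out = az.filter_expressed(m, 0.5)
    assert set(out.values.index) == {"kept", "edge"}
    assert len(az.filter_expressed(m, 0.0).values) == 3


def test_filter_count_matches_direct_recomputation():
    rng = np.random.default_rng(3)
    profiles = {f"g{i}": rng.uniform(0, 2, 5) for i in range(200)}
    m = make_matrix(profiles)
    out = az.filter_expressed(m, 0.5)
    want = sum(1 for v in profiles.values() if np.repeat(v, 5).mean() >= 0.5)
    assert len(out.values) == want


# ---------------------------------------------------------------------------
# differential expression gate
# ---------------------------------------------------------------------------

def test_no_signal_yields_empty_de_set():
    m = make_matrix({f"g{i}": [5.0] * 5 for i in range(20)})
    assert az.differential_genes(m) == set()


def test_large_step_change_is_called():
    m = make_matrix(
        {"flat": [4.0] * 5, "step": [1.0, 1.0, 1.0, 1.0, 8.0]}
    )
    # deterministic replicates -> zero variance handled as a certain call
    assert az.differential_genes(m) == {"step"}


def test_single_replicate_stage_rejected():
    m = make_matrix({"g": [1.0, 2.0, 3.0]}, n_reps=1)
    with pytest.raises(ValueError, match="replicates"):
        az.differential_genes(m)


def test_de_calibration_on_planted_fraction():
    """10% planted 8-fold shifts at moderate noise: high recall, bounded FDR."""
    rng = np.random.default_rng(9)
    profiles = {}
    truth = set()
    for i in range(300):
        g = f"g{i}"
        base = np.full(5, 5.0)
        if i < 30:
            base[3:] = 40.0
            truth.add(g)
        noisy = base[None].repeat(5, axis=0).T * rng.lognormal(0, 0.2, (5, 5))
        profiles[g] = noisy
    cols = [f"T{t}_R{r}" for t in range(1, 6) for r in range(1, 6)]
    import pandas as pd

    values = pd.DataFrame(
        {g: v.ravel() for g, v in profiles.items()}, index=cols
    ).T
    m = az.TimeCourseMatrix(values)
    de = az.differential_genes(m)
    recall = len(de & truth) / len(truth)
    fdr = len(de - truth) / max(len(de), 1)
    assert recall >= 0.9
    assert fdr <= 0.1


# ---------------------------------------------------------------------------
# signed network
# ---------------------------------------------------------------------------

def test_antiphase_profiles_yield_negative_edge_and_no_self_edges():
    m = make_matrix(
        {"tf": [1, 2, 3, 4, 5], "anti": [5, 4, 3, 2, 1], "flat": [3] * 5},
        tf_flags={"tf"},
    )
    gcn = az.pearson_network(m, {"tf"}, {"anti", "flat"})
    edges = {(a, b): s for a, b, r, s in gcn.edges.itertuples(index=False)}
    assert edges == {("tf", "anti"): "-"}


def test_constant_gene_forms_no_edge():
    m = make_matrix({"tf": [1, 2, 3, 4, 5], "const": [2] * 5}, tf_flags={"tf"})
    gcn = az.pearson_network(m, {"tf"}, {"const"})
    assert len(gcn.edges) == 0


def test_tightening_cutoffs_never_adds_edges(dataset, pipeline):
    sub = pipeline["sub"]
    tfs = set(dataset.catalog.tf_ids) & set(sub.gene_ids)
    genes = set(sub.gene_ids) - tfs
    loose = az.pearson_network(sub, tfs, genes, 0.81, -0.57)
    tight = az.pearson_network(sub, tfs, genes, 0.85, -0.65)
    as_set = lambda g: {(a, b, s) for a, b, r, s in g.edges.itertuples(index=False)}
    assert as_set(tight) <= as_set(loose)


def test_stored_edges_meet_cutoffs_and_recompute(dataset, pipeline):
    gcn, sub = pipeline["gcn"], pipeline["sub"]
    v = sub.values
    for a, b, r, s in gcn.edges.sample(50, random_state=0).itertuples(index=False):
        direct = np.corrcoef(v.loc[a], v.loc[b])[0, 1]
        assert direct == pytest.approx(r, abs=1e-9)
        assert (r >= gcn.pos_cutoff) if s == "+" else (r <= gcn.neg_cutoff)


def test_suggested_cutoffs_admit_planted_edges_and_are_deterministic(dataset, pipeline):
    sub = pipeline["sub"]
    tfs = set(dataset.catalog.tf_ids) & set(sub.gene_ids)
    genes = set(sub.gene_ids) - tfs
    got1 = az.suggest_cutoffs(sub, tfs, genes, n_permutations=50, seed=21)
    got2 = az.suggest_cutoffs(sub, tfs, genes, n_permutations=50, seed=21)
    assert got1 == got2
    pos, neg = got1
    # strongly planted cascade: every planted activator edge admitted
    assert pos <= 0.81 and neg >= -0.95
    with pytest.raises(ValueError):
        az.suggest_cutoffs(sub, tfs, genes, n_permutations=5, seed=1)


def test_pure_noise_matrix_suggests_conservative_cutoffs():
    rng = np.random.default_rng(17)
    profiles = {f"g{i}": rng.uniform(1, 10, (25,)) for i in range(80)}
    import pandas as pd

    cols = [f"T{t}_R{r}" for t in range(1, 6) for r in range(1, 6)]
    m = az.TimeCourseMatrix(pd.DataFrame(profiles, index=cols).T)
    tfs = {f"g{i}" for i in range(20)}
    genes = set(m.gene_ids) - tfs
    pos, neg = az.suggest_cutoffs(m, tfs, genes, n_permutations=50, seed=2)
    # under the null the suggested cutoffs must admit few or no real edges
    gcn = az.pearson_network(m, tfs, genes, pos, neg)
    assert len(gcn.edges) <= 2


# ---------------------------------------------------------------------------
# seed selection
# ---------------------------------------------------------------------------

def test_first_stage_specific_tf_selected_with_tie_rules():
    m = make_matrix(
        {
            "tfA": [10, 0.1, 0.1, 0.1, 0.1],
            "tfB": [3, 3, 3, 3, 3.1],
            "tfC": [10, 0.1, 0.1, 0.1, 0.1],
        },
        tf_flags={"tfA", "tfB", "tfC"},
    )
    assert az.select_seed(m, {"tfA", "tfB", "tfC"}) == "tfA"  # lexicographic tie
    assert az.select_seed(m, {"tfB", "tfC"}) == "tfC"
    with pytest.raises(ValueError):
        az.select_seed(make_matrix({"x": [0.1] * 5}, tf_flags={"x"}), {"x"})


def test_selected_seed_is_a_planted_first_level_tf(dataset, pipeline):
    assert dataset.truth.level_by_tf[pipeline["seed"]] == 1


# ---------------------------------------------------------------------------
# level assignment
# ---------------------------------------------------------------------------

def _toy_gcn(edge_list, tfs, genes=()):
    import pandas as pd

    edges = pd.DataFrame(edge_list, columns=["gene_a", "gene_b", "r", "sign"])
    return az.SignedGCN(edges, set(tfs), set(genes), 0.81, -0.57)


def test_bfs_chain_levels_and_shortcut():
    gcn = _toy_gcn(
        [("s", "b", 0.9, "+"), ("b", "c", 0.9, "+")], tfs={"s", "b", "c"}
    )
    lv = az.assign_levels(gcn, "s", min_nodes=0)
    assert lv.level_by_node == {"s": 1, "b": 2, "c": 3}
    gcn2 = _toy_gcn(
        [("s", "b", 0.85, "+"), ("s", "m", 0.9, "+"), ("m", "b", 0.9, "+")],
        tfs={"s", "b", "m"},
    )
    lv2 = az.assign_levels(gcn2, "s", min_nodes=0)
    assert lv2.level_by_node["b"] == 2  # direct edge beats the 2-step path


def test_small_level_terminates_construction():
    edges = [("s", f"a{i}", 0.9, "+") for i in range(25)]
    edges += [(f"a{0}", "lone", 0.9, "+")]
    gcn = _toy_gcn(edges, tfs={"s", "lone"} | {f"a{i}" for i in range(25)})
    lv = az.assign_levels(gcn, "s", min_nodes=20)
    assert 3 not in lv.level_by_node.values()  # level 3 held 1 node -> discarded
    assert "lone" not in lv.level_by_node


def test_seed_absent_raises(pipeline):
    with pytest.raises(ValueError):
        az.assign_levels(pipeline["gcn"], "no-such-tf")


def test_planted_levels_recovered_within_one(dataset, pipeline):
    truth = dataset.truth.level_by_tf
    got = pipeline["levels"].tf_levels()
    scored = [(truth[tf], lvl) for tf, lvl in got.items() if tf in truth]
    assert len(scored) >= 0.9 * len(truth)
    frac = np.mean([abs(t - l) <= 1 for t, l in scored])
    assert frac >= 0.9


def test_every_level_k_tf_links_to_level_k_minus_1(pipeline):
    gcn, levels = pipeline["gcn"], pipeline["levels"]
    g = gcn.positive_tf_graph()
    tfl = levels.tf_levels()
    for tf, lvl in tfl.items():
        if lvl == 1:
            continue
        assert any(tfl.get(nb) == lvl - 1 for nb in g.neighbors(tf))


# ---------------------------------------------------------------------------
# stage mapping
# ---------------------------------------------------------------------------

def test_level_peaking_at_first_stage_maps_to_initial():
    m = make_matrix({"a": [9, 2, 1, 1, 1], "b": [8, 3, 1, 1, 1]}, tf_flags={"a", "b"})
    gcn = _toy_gcn([("a", "b", 0.95, "+")], tfs={"a", "b"})
    lv = az.assign_levels(gcn, "a", min_nodes=0)
    rep = az.map_levels_to_stages(lv, m)
    assert all(v["group"] == "initial" for v in rep["levels"].values())


def test_monotone_cascade_maps_to_non_decreasing_stage_groups(pipeline):
    rep = pipeline["report"]
    order = {"initial": 0, "transitional": 1, "terminal": 2}
    series = [order[rep["levels"][l]["group"]] for l in sorted(rep["levels"])]
    assert series == sorted(series)
    # conservation: group tallies cover every assigned member
    total = sum(g["members"] for g in rep["groups"].values())
    assert total == len(pipeline["levels"].level_by_node)
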