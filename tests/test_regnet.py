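"""PWM scanning, direct-regulator rules, hierarchical chain enumeration and
binding-site filtering, against brute-force oracles and planted truth."""

import numpy as np
import pandas as pd
import pytest

import azaleanet as az

from .oracles import oracle_pwm_hits


def _pwm(consensus, family="MYB", motif_id="M1"):
    counts = np.full((4, len(consensus)), 1.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 97.0
    return az.PWM(motif_id, family, counts)


def _toy_gcn(edge_list, tfs, genes=()):
    edges = pd.DataFrame(edge_list, columns=["gene_a", "gene_b", "r", "sign"])
    return az.SignedGCN(edges, set(tfs), set(genes), 0.81, -0.57)


def _levels(d, tfs):
    return az.LevelAssignment(dict(d), set(tfs), seed="s", max_level=max(d.values()))


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def test_exact_consensus_found_once_at_max_threshold():
    rng = np.random.default_rng(1)
    cons = "ACGTAGGCTAAC"
    pwm = _pwm(cons)
    bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    seq = bg[:100] + cons + bg[100:]
    hits = az.pwm_scan(seq, pwm, threshold=1.0)
    assert [(h.offset, h.strand) for h in hits] == [(100, "+")]


def test_minus_strand_site_recovered():
    cons = "ACGTAGGCTAAC"
    pwm = _pwm(cons)
    seq = "T" * 40 + az.regnet.revcomp(cons) + "T" * 40
    hits = az.pwm_scan(seq, pwm, threshold=1.0)
    assert [(h.offset, h.strand) for h in hits] == [(40, "-")]


def test_reverse_complement_scan_mirrors_hits():
    rng = np.random.default_rng(2)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    pwm = _pwm("ACGTACGTACGA")
    fwd = az.pwm_scan(seq, pwm, threshold=0.6)
    rev = az.pwm_scan(az.regnet.revcomp(seq), pwm, threshold=0.6)
    flip = {"+": "-", "-": "+"}
    mirrored = sorted(
        (len(seq) - pwm.width - h.offset, flip[h.strand]) for h in rev
    )
    assert mirrored == sorted((h.offset, h.strand) for h in fwd)


@pytest.mark.parametrize("threshold", [0.6, 0.75, 0.9])
def test_hits_match_window_rescoring_oracle(threshold):
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    pwm = _pwm("AATTGGCCATGC")
    got = sorted((h.offset, h.strand) for h in az.pwm_scan(seq, pwm, threshold))
    assert got == oracle_pwm_hits(seq, pwm, threshold)


def test_short_promoter_yields_no_hits():
    assert az.pwm_scan("ACGT", _pwm("ACGTACGTACGA"), 0.8) == []


def test_jaspar_round_trip(tmp_path, dataset):
    path = tmp_path / "motifs.txt"
    pwms = sorted(dataset.pwms.values(), key=lambda p: p.motif_id)
    az.write_jaspar(pwms, path)
    back = az.read_jaspar(path)
    assert [p.motif_id for p in back] == [p.motif_id for p in pwms]
    assert all(
        np.array_equal(a.counts, b.counts) and a.family == b.family
        for a, b in zip(back, pwms)
    )


# ---------------------------------------------------------------------------
# direct regulators
# ---------------------------------------------------------------------------

def test_level_rule_and_sign_separation():
    gcn = _toy_gcn(
        [
            ("early", "E", 0.9, "+"),
            ("late", "E", 0.95, "+"),
            ("rep", "E", -0.8, "-"),
        ],
        tfs={"early", "late", "rep"},
        genes={"E"},
    )
    lv = _levels({"early": 2, "late": 5, "rep": 1, "E": 2}, {"early", "late", "rep"})
    regs = az.direct_regulators(gcn, lv, "E")
    assert [t for t, _ in regs.activators] == ["early"]
    assert [t for t, _ in regs.repressors] == ["rep"]
    with pytest.raises(ValueError, match="level"):
        az.direct_regulators(gcn, lv, "unleveled")


# ---------------------------------------------------------------------------
# chain enumeration
# ---------------------------------------------------------------------------

def test_single_path_chain_enumerated():
    gcn = _toy_gcn(
        [("W", "G", 0.9, "+"), ("G", "M", 0.9, "+"), ("M", "E", 0.92, "+")],
        tfs={"W", "G", "M"},
        genes={"E"},
    )
    lv = _levels({"W": 1, "G": 2, "M": 3, "E": 3}, {"W", "G", "M"})
    chains = az.regulator_chains(gcn, lv, "E")
    assert {c.tfs for c in chains} == {("M",), ("G", "M"), ("W", "G", "M")}
    assert max(c.order for c in chains) == 3


def test_no_tf_tf_edges_gives_only_first_order_chains():
    gcn = _toy_gcn(
        [("A", "E", 0.9, "+"), ("B", "E", 0.85, "+")], tfs={"A", "B"}, genes={"E"}
    )
    lv = _levels({"A": 1, "B": 2, "E": 2}, {"A", "B"})
    chains = az.regulator_chains(gcn, lv, "E")
    assert all(c.order == 1 for c in chains)


def test_chain_levels_non_decreasing_toward_target(pipeline, dataset):
    target = dataset.truth.chains[0].target
    chains = az.regulator_chains(pipeline["gcn"], pipeline["levels"], target)
    lvl = pipeline["levels"].level_by_node
    for c in chains[:200]:
        seq = [lvl[t] for t in c.tfs] + [lvl[c.target]]
        assert seq == sorted(seq)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_chain_set_equals_exhaustive_path_enumeration(seed):
    import networkx as nx

    rng = np.random.default_rng(seed)
    tfs = [f"t{i}" for i in range(12)]
    lv_map = {t: int(rng.integers(1, 5)) for t in tfs}
    lv_map["E"] = 4
    edges = []
    for i in range(len(tfs)):
        for j in range(i + 1, len(tfs)):
            if rng.random() < 0.3:
                edges.append((tfs[i], tfs[j], 0.85 + 0.1 * rng.random(), "+"))
    for t in tfs:
        if rng.random() < 0.4:
            edges.append((t, "E", 0.9, "+"))
    gcn = _toy_gcn(edges, tfs=set(tfs), genes={"E"})
    lv = _levels(lv_map, set(tfs))
    got = {c.tfs for c in az.regulator_chains(gcn, lv, "E", max_order=3)}

    # oracle: enumerate all simple paths in the undirected positive graph
    g = nx.Graph()
    for a, b, r, s in edges:
        g.add_edge(a, b, r=r)
    want = set()
    directs = [
        t for t in tfs
        if g.has_edge(t, "E") and lv_map[t] <= lv_map["E"]
    ]
    tf_graph = g.subgraph(tfs)
    for d in directs:
        for src in tf_graph.nodes:
            if src == d:
                continue
            for path in nx.all_simple_paths(tf_graph, src, d, cutoff=2):
                levels_seq = [lv_map[x] for x in path]
                if levels_seq == sorted(levels_seq):
                    want.add(tuple(path))
        want.add((d,))
    assert got == want


# ---------------------------------------------------------------------------
# binding-site filtering and planted recovery
# ---------------------------------------------------------------------------

def test_binding_filter_keeps_only_supported_family():
    gcn = _toy_gcn(
        [("MYBx", "E", 0.9, "+"), ("C2H2x", "E", 0.88, "+")],
        tfs={"MYBx", "C2H2x"},
        genes={"E"},
    )
    lv = _levels({"MYBx": 3, "C2H2x": 3, "E": 3}, {"MYBx", "C2H2x"})
    chains = az.regulator_chains(gcn, lv, "E")
    hits = [az.MotifHit("E", "M9", "C2H2", 10, "+", 12.0)]
    fam = {"MYBx": "MYB", "C2H2x": "C2H2"}
    chains = az.filter_chains_by_binding(chains, hits, fam)
    supported = {c.direct for c in chains if c.supported}
    demoted = {c.direct for c in chains if c.demoted}
    assert supported == {"C2H2x"} and demoted == {"MYBx"}
    # no hits at all -> nothing supported
    chains2 = az.filter_chains_by_binding(az.regulator_chains(gcn, lv, "E"), [], fam)
    assert not any(c.supported for c in chains2)
    # unknown family never supported
    chains3 = az.filter_chains_by_binding(
        az.regulator_chains(gcn, lv, "E"), hits, {"C2H2x": "C2H2"}
    )
    assert any(c.unknown_family for c in chains3)


def test_planted_chains_supported_with_perfect_precision(noiseless_dataset):
    ds = noiseless_dataset
    m = az.filter_expressed(ds.matrix)
    de = az.differential_genes(m)
    tfs = set(ds.catalog.tf_ids) & de
    sub = m.subset(de)
    gcn = az.pearson_network(sub, tfs, de - tfs)
    seed_tf = az.select_seed(sub, tfs)
    lv = az.assign_levels(gcn, seed_tf)
    fam = ds.catalog.family_of()
    hits = az.scan_promoters(ds.promoters, ds.pwms.values(), threshold=1.0)
    planted_direct = {c.tfs[-1] for c in ds.truth.chains}
    target = ds.truth.chains[0].target
    chains = az.regulator_chains(gcn, lv, target)
    chains = az.filter_chains_by_binding(chains, hits, fam)
    supported_direct = {c.direct for c in chains if c.supported}
    assert supported_direct == planted_direct  # precision = recall = 1
    planted_paths = {c.tfs for c in ds.truth.chains}
    assert planted_paths <= {c.tfs for c in chains if c.supported}


# ---------------------------------------------------------------------------
# pathway sub-networks
# ---------------------------------------------------------------------------

def test_family_tally_on_toy_network():
    gcn = _toy_gcn(
        [("M", "E", 0.9, "+"), ("B", "E", 0.85, "+")], tfs={"M", "B"}, genes={"E"}
    )
    lv = _levels({"M": 1, "B": 1, "E": 2}, {"M", "B"})
    lv.level_to_group = {1: "initial", 2: "initial"}
    sub = az.pathway_subnetwork(gcn, lv, {"E"}, "initial", {"M": "MYB", "B": "bHLH"})
    assert sub.enzyme_genes == ["E"]
    assert sub.family_tally == {"MYB": 1, "bHLH": 1}
    empty = az.pathway_subnetwork(gcn, lv, {"nope"}, "initial", {})
    assert empty.enzyme_genes == [] and len(empty.edges) == 0


def test_planted_pathway_subnetwork_recovered(pipeline, dataset):
    lv, gcn = pipeline["levels"], pipeline["gcn"]
    anth = set(dataset.catalog.pathway_genes("anthocyanin"))
    groups = {lv.level_to_group[l] for g in anth
              if (l := lv.level_by_node.get(g)) is not None}
    found = set()
    for grp in groups:
        sub = az.pathway_subnetwork(gcn, lv, anth, grp, dataset.catalog.family_of())
        found |= set(sub.enzyme_genes)
        for e in sub.enzyme_genes:
            assert (gcn.edges["gene_a"] == e).any() or (gcn.edges["gene_b"] == e).any()
    assert found == {g for g in anth if lv.level_by_node.get(g) is not None}
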