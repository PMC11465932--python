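"""Network loading, BN/GN classification and the shortest-path extension."""

import networkx as nx
import numpy as np
import pytest

from gwasnet.exceptions import ValidationError
from gwasnet.interactome import (
    classify_bn_gn, fit_power_law, load_network, network_summary, rbsp_extend,
)

from oracles import bf_rbsp_ynset


def test_load_network_dedupes_and_reports(tmp_path):
    path = tmp_path / "edges.tsv"
    path.write_text("A\tB\nB\tA\nA\tA\n")
    graph, report = load_network(path)
    assert graph.number_of_edges() == 1
    assert report.n_self_loops_removed == 1
    assert report.n_duplicates_removed == 1
    assert "A" in graph  # self-loop node retained


def test_load_network_empty_and_malformed(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    graph, report = load_network(empty)
    assert graph.number_of_nodes() == 0 and report.n_edges == 0
    bad = tmp_path / "bad.tsv"
    bad.write_text("A\tB\nA\tB\tC\n")
    with pytest.raises(ValidationError, match="bad.tsv:2"):
        load_network(bad)


def test_sif_and_tsv_equivalent(tmp_path):
    sif = tmp_path / "net.sif"
    sif.write_text("A\tpp\tB\tC\nB\tpp\tC\n")
    tsv = tmp_path / "net.tsv"
    tsv.write_text("A\tB\nA\tC\nB\tC\n")
    g1, _ = load_network(sif)
    g2, _ = load_network(tsv)
    assert set(g1.edges) == set(g2.edges)


def test_classify_triangle_plus_isolate():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    g.add_edge("D", "X")  # D's only neighbor is not a GWAS protein
    cls = classify_bn_gn(g, {"A", "B", "C", "D"})
    assert cls.nodes_with("BN") == {"A", "B", "C"}
    assert cls.nodes_with("GN") == {"D"}


def test_classify_all_isolated_tie_break():
    g = nx.Graph()
    g.add_nodes_from(["C", "A", "B"])
    cls = classify_bn_gn(g, {"A", "B", "C"})
    # deterministic: the lexicographically smallest singleton wins
    assert cls.nodes_with("BN") == {"A"}
    assert cls.nodes_with("GN") == {"B", "C"}


def test_classify_drops_absent_proteins():
    g = nx.Graph([("A", "B")])
    cls = classify_bn_gn(g, {"A", "B", "ZZZ"})
    assert cls.dropped == {"ZZZ"}


def test_classify_equals_brute_force_components():
    rng = np.random.default_rng(5)
    g = nx.gnp_random_graph(30, 0.07, seed=9)
    gwas = set(rng.choice(30, size=12, replace=False).tolist())
    cls = classify_bn_gn(g, gwas)
    induced = g.subgraph(gwas)
    comps = sorted(nx.connected_components(induced),
                   key=lambda c: (-len(c), min(str(n) for n in c)))
    assert cls.nodes_with("BN") == comps[0]
    assert cls.nodes_with("GN") == set().union(*comps[1:]) if len(comps) > 1 \
        else cls.nodes_with("GN") == set()


def test_rbsp_single_path():
    g = nx.Graph([("A", "B"), ("C", "X"), ("X", "A")])
    cls = classify_bn_gn(g, {"A", "B", "C"})
    res = rbsp_extend(g, cls)
    assert res.yn_set == {"X"}
    assert set(res.graph.nodes) == {"A", "B", "C", "X"}
    assert nx.is_connected(res.graph)
    assert res.gn_distance == {"C": 2}


def test_rbsp_tie_case_policies():
    g = nx.Graph([("A", "B"), ("C", "X1"), ("X1", "A"),
                  ("C", "X2"), ("X2", "B")])
    cls = classify_bn_gn(g, {"A", "B", "C"})
    all_res = rbsp_extend(g, cls, path_policy="all_shortest")
    assert all_res.yn_set == {"X1", "X2"}
    single_res = rbsp_extend(g, cls, path_policy="single")
    assert len(single_res.yn_set) == 1
    assert single_res.yn_set < all_res.yn_set


def test_rbsp_adjacent_gn_contributes_no_yn():
    g = nx.Graph([("A", "B"), ("C", "A"), ("C", "X")])
    # C connects directly to the BN component: no intermediate needed
    cls = classify_bn_gn(g, {"A", "B"})
    cls.labels["C"] = "GN"
    cls.component_id["C"] = 1
    res = rbsp_extend(g, cls)
    assert res.yn_set == set()
    assert res.gn_distance["C"] == 1


def test_rbsp_unreachable_gn_retained():
    g = nx.Graph([("A", "B"), ("D", "E")])
    cls = classify_bn_gn(g, {"A", "B", "D"})
    res = rbsp_extend(g, cls)
    assert res.unreachable_gns == {"D"}
    assert "D" in res.graph


def test_rbsp_requires_bns():
    g = nx.Graph([("A", "B")])
    cls = classify_bn_gn(g, set())
    with pytest.raises(ValidationError):
        rbsp_extend(g, cls)


def test_rbsp_matches_brute_force_enumeration():
    rng = np.random.default_rng(17)
    for seed in range(5):
        g = nx.gnp_random_graph(50, 0.06, seed=100 + seed)
        gwas = set(rng.choice(50, size=12, replace=False).tolist())
        cls = classify_bn_gn(g, gwas)
        if not cls.nodes_with("BN"):
            continue
        res = rbsp_extend(g, cls)
        assert res.yn_set == bf_rbsp_ynset(
            g, cls.nodes_with("BN"), cls.nodes_with("GN"))


def test_rbsp_preserves_distances_and_induced_subgraph():
    g = nx.gnp_random_graph(40, 0.08, seed=4)
    gwas = set(range(0, 40, 4))
    cls = classify_bn_gn(g, gwas)
    res = rbsp_extend(g, cls)
    bns = cls.nodes_with("BN")
    # the extension preserves each reachable GN's distance to the BN set
    for gn, d in res.gn_distance.items():
        d_ext = min(nx.shortest_path_length(res.graph, gn, b)
                    for b in bns
                    if nx.has_path(res.graph, gn, b))
        assert d_ext == d
    # nothing from the BN∪GN induced subgraph is lost
    induced = g.subgraph(bns | cls.nodes_with("GN"))
    assert set(induced.edges) <= set(res.graph.edges) | \
        {(v, u) for u, v in res.graph.edges}


def test_network_summary_star_histogram():
    g = nx.star_graph(10)
    summary = network_summary(g)
    assert summary["degree_histogram"] == {10: 1, 1: 10}
    assert summary["n_nodes"] == 11 and summary["n_edges"] == 10


def test_hub_count_uses_reference_degrees():
    ref = nx.star_graph(350)
    sub = ref.subgraph([0, 1, 2, 3])
    summary = network_summary(sub, reference=ref, hub_threshold=300)
    assert summary["n_reference_hubs"] == 1  # only the star center


def test_power_law_perfect_fit():
    fit = fit_power_law({1: 64, 2: 16, 4: 4, 8: 1})  # P(k) ∝ k^-2 exactly
    assert fit["r2"] == pytest.approx(1.0)
    assert fit["slope"] == pytest.approx(-2.0)


def test_power_law_needs_three_degrees():
    with pytest.warns(UserWarning, match="fit skipped"):
        assert fit_power_law({1: 5, 2: 3}) is None


def test_barabasi_albert_scale_free_fit():
    g = nx.barabasi_albert_graph(2000, 3, seed=42)
    fit = network_summary(g)["power_law"]
    assert fit["r2"] >= 0.8
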