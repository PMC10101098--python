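"""STRING table handling, GRN construction, core extraction, graph export."""

import itertools

import networkx as nx
import numpy as np
import pytest

from velvet_grn.grn_build import (
    build_grn,
    common_grn_statuses,
    core_section,
    export_graph,
    map_edges_to_genes,
    read_alias,
    read_graphml,
    read_string_links,
)
from velvet_grn.target_classify import TargetRecord


def _links_file(tmp_path, lines):
    p = tmp_path / "links.tsv"
    p.write_text("protein1 protein2 combined_score\n" + "".join(l + "\n" for l in lines))
    return p


def test_read_links_dedup_swap_keeps_max_and_drops_self_loops(tmp_path):
    p = _links_file(tmp_path, ["p1 p2 300", "p2 p1 250", "p1 p1 900"])
    assert read_string_links(p) == [("p1", "p2", 300)]


def test_read_links_non_integer_score_names_line(tmp_path):
    p = _links_file(tmp_path, ["p1 p2 300", "p1 p3 high"])
    with pytest.raises(ValueError, match=":3"):
        read_string_links(p)


def test_alias_mapping_drops_unmapped_edges(tmp_path):
    alias_p = tmp_path / "alias.tsv"
    alias_p.write_text("protein_id\tgene_id\np1\tg1\np2\tg2\n")
    alias = read_alias(alias_p)
    edges, dropped = map_edges_to_genes(
        [("p1", "p2", 300), ("p1", "p3", 500)], alias)
    assert edges == [("g1", "g2", 300)] and dropped == 1


def _statuses(direct=(), putative=()):
    return {**{g: "direct" for g in direct}, **{g: "putative_direct" for g in putative}}


def test_build_grn_score_threshold_inclusive():
    st = _statuses(direct=["t1", "t2"])
    keep = build_grn(st, [("t1", "t2", 150)], "reg")
    drop = build_grn(st, [("t1", "t2", 149)], "reg")
    assert keep.number_of_edges() == 1 and drop.number_of_edges() == 0


def test_build_grn_both_endpoints_rule_and_node_set():
    st = _statuses(direct=["t1"], putative=["t2"])
    g = build_grn(st, [("t1", "other", 900), ("t1", "t2", 400)], "reg")
    assert set(g.nodes) == {"t1", "t2"}
    assert g.nodes["t1"]["status"] == "direct"
    assert g.nodes["t2"]["status"] == "putative_direct"


def test_build_grn_planted_clique_counts():
    targets = [f"t{i}" for i in range(5)]
    edges = [(a, b, 500) for a, b in itertools.combinations(targets, 2)]
    edges += [("x1", "x2", 50), ("t0", "x1", 100), ("t1", "t2", 20)]
    g = build_grn(_statuses(direct=targets), edges, "reg")
    assert (g.number_of_nodes(), g.number_of_edges()) == (5, 10)


def _brute_grn(statuses, edges, regulator, min_score=150):
    allowed = {g for g, s in statuses.items()
               if s in ("direct", "putative_direct")} | {regulator}
    kept = {tuple(sorted((a, b))): s for a, b, s in edges
            if s >= min_score and a in allowed and b in allowed and a != b}
    nodes = {n for e in kept for n in e}
    return nodes, set(kept)


def test_build_grn_equals_bruteforce_on_random_graphs():
    rng = np.random.default_rng(17)
    for _ in range(40):
        n = int(rng.integers(2, 30))
        genes = [f"g{i}" for i in range(n)]
        statuses = {}
        for g in genes:
            r = rng.random()
            if r < 0.4:
                statuses[g] = "direct"
            elif r < 0.7:
                statuses[g] = "putative_direct"
        pairs = list(itertools.combinations(genes, 2))
        take = rng.random(len(pairs)) < 0.3
        edges = [(a, b, int(rng.integers(0, 1000)))
                 for (a, b), t in zip(pairs, take) if t]
        grn = build_grn(statuses, edges, "reg")
        nodes, kept = _brute_grn(statuses, edges, "reg")
        assert set(grn.nodes) == nodes
        assert {tuple(sorted(e)) for e in grn.edges} == kept
        assert all(d["score"] >= 150 for _, _, d in grn.edges(data=True))
        # raising the threshold never grows the graph
        higher = build_grn(statuses, edges, "reg", min_score=400)
        assert higher.number_of_nodes() <= grn.number_of_nodes()
        assert higher.number_of_edges() <= grn.number_of_edges()


def _toy_graph(edges, statuses=None):
    g = nx.Graph(regulator_id="a")
    for a, b in edges:
        g.add_edge(a, b, score=500)
    for n in g.nodes:
        g.nodes[n]["status"] = (statuses or {}).get(n, "direct")
    return g


def test_core_section_examples():
    star = _toy_graph([("hub", x) for x in "bcd"])
    assert set(core_section(star, ["hub"]).nodes) == {"hub", "b", "c", "d"}

    path = _toy_graph([("a", "b"), ("b", "c")])
    core = core_section(path, ["a"])
    assert set(core.nodes) == {"a", "b"} and set(map(tuple, map(sorted, core.edges))) == {("a", "b")}

    tri = _toy_graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
    core = core_section(tri, ["a"])
    assert set(core.nodes) == {"a", "b", "c"}
    assert {tuple(sorted(e)) for e in core.edges} == {("a", "b"), ("a", "c"), ("b", "c")}


def test_core_section_idempotent_and_seed_handling():
    rng = np.random.default_rng(23)
    g = nx.gnp_random_graph(25, 0.15, seed=4)
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
    for a, b in g.edges:
        g.edges[a, b]["score"] = 500
    for n in g.nodes:
        g.nodes[n]["status"] = "direct"
    seeds = ["g0", "g5"]
    once = core_section(g, seeds)
    twice = core_section(once, seeds)
    assert set(once.nodes) == set(twice.nodes)
    assert set(once.edges) == set(twice.edges)
    with pytest.raises(ValueError):
        core_section(g, ["missing"])
    # an absent seed among present ones is skipped, not fatal
    assert set(core_section(g, ["g0", "missing"]).nodes) == set(core_section(g, ["g0"]).nodes)


def _t(gene, status, bound=True):
    return TargetRecord(gene, bound, status, "up" if status == "direct" else "none")


def test_common_grn_statuses_rules():
    a = [_t("g1", "direct"), _t("g2", "direct"), _t("g3", "putative_direct"),
         _t("g4", "deg_only", bound=False)]
    b = [_t("g1", "direct"), _t("g2", "putative_direct"), _t("g5", "direct")]
    st = common_grn_statuses(a, b)
    assert st == {"g1": "direct", "g2": "putative_direct"}
    # symmetric universe
    assert set(common_grn_statuses(b, a)) == set(st)


def test_export_and_graphml_round_trip(tmp_path):
    g = _toy_graph([("g1", "g2")], {"g1": "direct", "g2": "putative_direct"})
    paths = export_graph(g, tmp_path / "net")
    assert paths["sif"].read_text() == "g1\tpp\tg2\n"
    back = read_graphml(paths["graphml"])
    assert set(back.nodes) == set(g.nodes)
    assert back.nodes["g1"]["status"] == "direct"
    assert back.edges["g1", "g2"]["score"] == 500
    nodes_tsv = paths["nodes"].read_text()
    assert "g1\tdirect" in nodes_tsv


def test_export_empty_graph_refused(tmp_path):
    with pytest.raises(ValueError):
        export_graph(nx.Graph(), tmp_path / "empty")
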