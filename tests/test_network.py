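"""Bipartite network construction, filtering, consensus and export."""

import networkx as nx
import pandas as pd
import pytest

from mirnet.network import (
    TargetEdgeTable,
    annotate_nodes,
    build_bipartite,
    consensus_targets,
    export_network,
    filter_min_targeting,
    load_network,
    network_summary,
)
from mirnet.worked_example import CONSENSUS_TARGETS, prediction_tables


def table(rows):
    return TargetEdgeTable(pd.DataFrame(rows,
                                        columns=["mirna", "gene", "db"]))


def random_network(rng, n_mirnas=10, n_genes=30, n_edges=60):
    mirnas = [f"miR-{i}" for i in range(n_mirnas)]
    genes = [f"G{i}" for i in range(n_genes)]
    rows = set()
    while len(rows) < n_edges:
        rows.add((mirnas[rng.integers(n_mirnas)],
                  genes[rng.integers(n_genes)], "db1"))
    directions = {m: ("up" if i % 2 else "down")
                  for i, m in enumerate(mirnas)}
    return build_bipartite(table(sorted(rows)), directions)


class TestTargetEdgeTable:
    def test_duplicate_triples_collapse(self):
        t = table([("miR-1", "G1", "db1"), ("miR-1", "G1", "db1")])
        assert len(t.records) == 1

    def test_empty_id_rejected(self):
        with pytest.raises(ValueError, match="empty id"):
            table([("miR-1", "", "db1")])

    def test_tsv_round_trip(self, tmp_path):
        t = table([("miR-1", "G1", "db1"), ("miR-2", "G2", "db2")])
        t.write_tsv(tmp_path / "edges.tsv")
        back = TargetEdgeTable.read_tsv(tmp_path / "edges.tsv")
        pd.testing.assert_frame_equal(back.records, t.records)


class TestBuildBipartite:
    def test_restricts_to_given_mirnas(self):
        t = table([("miR-1", "G1", "db1"), ("miR-1", "G2", "db1"),
                   ("miR-9", "G3", "db1")])
        net = build_bipartite(t, {"miR-1": "up", "miR-2": "down"})
        assert net.number_of_edges() == 2
        assert "miR-9" not in net

    def test_multi_database_support_collapses_to_one_edge(self):
        t = table([("miR-1", "G1", "db1"), ("miR-1", "G1", "db2")])
        net = build_bipartite(t, {"miR-1": "up"})
        assert net.number_of_edges() == 1
        assert net.edges["miR-1", "G1"]["support"] == 2

    def test_isolated_mirnas_retained(self):
        t = table([("miR-1", "G1", "db1")])
        net = build_bipartite(t, {"miR-1": "up", "miR-2": "down"})
        assert net.degree("miR-2") == 0

    def test_missing_direction_is_an_error(self):
        t = table([("miR-1", "G1", "db1")])
        with pytest.raises(ValueError, match="direction"):
            build_bipartite(t, {"miR-1": "sideways"})

    def test_counts_match_brute_force_tally(self, rng):
        mirnas = [f"miR-{i}" for i in range(5)]
        rows = sorted({(mirnas[rng.integers(5)], f"G{rng.integers(20)}",
                        f"db{rng.integers(3)}") for _ in range(80)})
        directions = {m: "up" for m in mirnas}
        net = build_bipartite(table(rows), directions)
        pairs = {(m, g) for m, g, _ in rows}
        genes = {g for _, g in pairs}
        assert net.number_of_edges() == len(pairs)
        assert network_summary(net)["n_genes"] == len(genes)
        for m, g in pairs:
            assert net.edges[m, g]["support"] == \
                len({db for mm, gg, db in rows if (mm, gg) == (m, g)})

    def test_bipartite_structure(self, rng):
        net = random_network(rng)
        types = nx.get_node_attributes(net, "node_type")
        for u, v in net.edges:
            assert {types[u], types[v]} == {"mirna", "gene"}


class TestFilterMinTargeting:
    def test_singly_targeted_gene_removed_at_k2(self):
        t = table([("miR-1", "G1", "db1"), ("miR-1", "G2", "db1"),
                   ("miR-2", "G2", "db1")])
        net = filter_min_targeting(
            build_bipartite(t, {"miR-1": "up", "miR-2": "down"}), 2)
        assert "G1" not in net and "G2" in net
        assert "miR-1" in net  # miRNAs kept regardless of degree

    def test_k1_is_identity(self, rng):
        net = random_network(rng)
        filtered = filter_min_targeting(net, 1)
        assert nx.utils.graphs_equal(net, filtered)

    def test_idempotent(self, rng):
        net = random_network(rng)
        once = filter_min_targeting(net, 2)
        twice = filter_min_targeting(once, 2)
        assert nx.utils.graphs_equal(once, twice)

    def test_matches_brute_force_degree_recount(self, rng):
        net = random_network(rng)
        filtered = filter_min_targeting(net, 2)
        keep = {g for g, d in net.nodes(data=True)
                if d["node_type"] == "gene" and len(list(net.neighbors(g))) >= 2}
        genes_left = {g for g, d in filtered.nodes(data=True)
                      if d["node_type"] == "gene"}
        assert genes_left == keep

    def test_k_below_one_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 1"):
            filter_min_targeting(random_network(rng), 0)


class TestConsensusTargets:
    def test_published_consensus_for_mir141(self):
        tables = prediction_tables()
        assert consensus_targets(tables, "miR-141", 3) == \
            set(CONSENSUS_TARGETS["miR-141"]) == {"Yaf2", "Ulk2", "Ccne2"}

    def test_published_consensus_for_mir377(self):
        tables = prediction_tables()
        result = consensus_targets(tables, "miR-377", 3)
        assert result == set(CONSENSUS_TARGETS["miR-377"])
        assert len(result) == 8

    def test_min_one_is_union(self):
        tables = prediction_tables(n_decoys_per_db=2)
        union = set().union(*(t.genes_of("miR-141") for t in tables))
        assert consensus_targets(tables, "miR-141", 1) == union

    def test_monotone_decreasing_in_min_databases(self):
        tables = prediction_tables()
        sets = [consensus_targets(tables, "miR-377", k) for k in (1, 2, 3)]
        assert sets[2] <= sets[1] <= sets[0]

    def test_unknown_mirna_gives_empty_set(self):
        assert consensus_targets(prediction_tables(), "miR-none") == set()

    def test_support_never_exceeds_database_count(self):
        net = build_bipartite(prediction_tables(),
                              {"miR-141": "up", "miR-377": "down"})
        assert all(d["support"] <= 3 for _, _, d in net.edges(data=True))


class TestAnnotateNodes:
    def test_membership_sets_flags(self):
        t = table([("miR-1", "G1", "db1"), ("miR-1", "G2", "db1")])
        net = build_bipartite(t, {"miR-1": "up"})
        net = annotate_nodes(net, {"wnt": {"G1"}}, {"wnt": "tgfb_wnt"})
        assert net.nodes["G1"]["tgfb_wnt"] is True
        assert net.nodes["G2"]["tgfb_wnt"] is False

    def test_empty_collection_flags_all_false(self):
        t = table([("miR-1", "G1", "db1")])
        net = build_bipartite(t, {"miR-1": "up"})
        net = annotate_nodes(net, {}, {"missing": "flag"})
        assert net.nodes["G1"]["flag"] is False

    def test_flags_equal_membership_predicate(self, rng):
        net = random_network(rng)
        genes = [n for n, d in net.nodes(data=True)
                 if d["node_type"] == "gene"]
        chosen = set(rng.choice(genes, size=len(genes) // 2, replace=False))
        net = annotate_nodes(net, {"s": chosen}, {"s": "hit"})
        for g in genes:
            assert net.nodes[g]["hit"] == (g in chosen)


class TestExport:
    def test_single_edge_sif_line(self, tmp_path):
        t = table([("miR-x", "geneY", "db1")])
        net = build_bipartite(t, {"miR-x": "up"})
        path = tmp_path / "net.sif"
        export_network(net, path)
        assert path.read_text() == "miR-x\ttargets\tgeneY\n"

    def test_graphml_round_trip_preserves_everything(self, tmp_path, rng):
        net = random_network(rng)
        net = annotate_nodes(net, {"s": {"G1", "G5"}}, {"s": "tgfb_wnt"})
        path = tmp_path / "net.graphml"
        export_network(net, path)
        back = load_network(path)
        assert set(back.nodes) == set(net.nodes)
        assert set(map(frozenset, back.edges)) == \
            set(map(frozenset, net.edges))
        for n in net.nodes:
            assert dict(back.nodes[n]) == dict(net.nodes[n])
        for u, v in net.edges:
            assert back.edges[u, v]["support"] == net.edges[u, v]["support"]

    def test_unknown_format_rejected(self, tmp_path, rng):
        with pytest.raises(ValueError, match="format"):
            export_network(random_network(rng), tmp_path / "net.xyz")
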