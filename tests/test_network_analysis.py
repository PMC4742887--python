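"""Interaction-graph classification vs. exhaustive two-hop enumeration."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from myoscreen.network_analysis import (
    DEFAULT_MRFS,
    MOUSE_HUMAN_OVERRIDES,
    classify_regulators,
    export_subnetwork,
    merge_graphs,
    read_edge_list,
    read_sif,
    summarize_network,
)
from myoscreen.screen_data import ScreenFormatError, ScreenValidationError


def graph_from_edges(edges):
    g = nx.Graph()
    g.add_edges_from((a.upper(), b.upper()) for a, b in edges)
    return g


def edge_set(graph):
    return {tuple(sorted(e)) for e in graph.edges}


class TestReadEdgeList:
    def test_dedup_and_self_loop_removal(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\nB\tA\nA\tA\n")
        graph = read_edge_list(path)
        assert edge_set(graph) == {("A", "B")}

    def test_symbols_are_normalized(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("src\tmyod1\n")
        assert edge_set(read_edge_list(path)) == {("MYOD1", "SRC")}

    def test_mouse_to_human_override_map(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("Src\tMyod\n")
        graph = read_edge_list(path, symbol_map=MOUSE_HUMAN_OVERRIDES)
        assert edge_set(graph) == {("MYOD1", "SRC")}

    def test_header_is_auto_detected(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("Official Symbol A\tOfficial Symbol B\nSRC\tMYF5\n")
        assert edge_set(read_edge_list(path)) == {("MYF5", "SRC")}

    def test_single_column_is_a_format_error(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A-B\n")
        with pytest.raises(ScreenFormatError):
            read_edge_list(path)

    def test_merge_is_edge_union_with_provenance(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text("A\tB\nB\tC\n")
        p2.write_text("B\tC\nC\tD\n")
        merged = merge_graphs(read_edge_list(p1), read_edge_list(p2))
        assert edge_set(merged) == {("A", "B"), ("B", "C"), ("C", "D")}
        assert merged.edges["B", "C"]["sources"] == {"a.tsv", "b.tsv"}

    def test_row_order_invariance(self, tmp_path):
        rows = ["A\tB", "C\tD", "B\tC", "A\tD"]
        p1, p2 = tmp_path / "f.tsv", tmp_path / "r.tsv"
        p1.write_text("\n".join(rows) + "\n")
        p2.write_text("\n".join(reversed(rows)) + "\n")
        assert edge_set(read_edge_list(p1)) == edge_set(read_edge_list(p2))


class TestClassifyRegulators:
    def test_direct_connection(self):
        graph = graph_from_edges([("CSNK2A2", "MYF5")])
        cls = classify_regulators(graph, ["Csnk2a2"])
        assert cls.pairs[("CSNK2A2", "MYF5")].connection == "direct"
        assert cls.kinase_labels["CSNK2A2"] == "direct"

    def test_minimal_two_hop_is_semi_direct(self):
        graph = graph_from_edges([("K1", "X"), ("X", "MYOD1")])
        cls = classify_regulators(graph, ["K1"])
        pc = cls.pairs[("K1", "MYOD1")]
        assert pc.connection == "semi_direct"
        assert pc.intermediaries == frozenset({"X"})

    def test_absent_kinases_are_flagged(self):
        graph = graph_from_edges([("K1", "MYF5")])
        cls = classify_regulators(graph, ["K1", "K2"])
        assert cls.absent_from_graph == frozenset({"K2"})
        assert cls.kinase_labels["K2"] == "unconnected"

    def test_other_kinases_cannot_be_intermediaries_by_default(self):
        graph = graph_from_edges([("K1", "K2"), ("K2", "MYOG")])
        cls = classify_regulators(graph, ["K1", "K2"])
        assert cls.pairs[("K1", "MYOG")].connection == "unconnected"
        relaxed = classify_regulators(
            graph, ["K1", "K2"], allow_hub_intermediaries=True
        )
        assert relaxed.pairs[("K1", "MYOG")].connection == "semi_direct"

    def test_overlap_with_mrfs_rejected(self):
        with pytest.raises(ScreenValidationError):
            classify_regulators(nx.Graph(), ["MYOG", "K1"])

    def test_direct_to_one_mrf_can_be_semi_direct_to_another(self):
        graph = graph_from_edges(
            [("K1", "MYF5"), ("K1", "X"), ("X", "MYOD1")]
        )
        cls = classify_regulators(graph, ["K1"])
        assert cls.pairs[("K1", "MYF5")].connection == "direct"
        assert cls.pairs[("K1", "MYOD1")].connection == "semi_direct"

    def test_adding_edges_never_demotes_a_label(self):
        rank = {"unconnected": 0, "semi_direct": 1, "direct": 2}
        rng = np.random.default_rng(8)
        nodes = [f"N{i}" for i in range(12)] + list(DEFAULT_MRFS) + ["K1", "K2"]
        for _ in range(50):
            pool = list(itertools.combinations(nodes, 2))
            idx = rng.choice(len(pool), size=25, replace=False)
            edges = [pool[i] for i in idx]
            g1 = graph_from_edges(edges[:15])
            g2 = graph_from_edges(edges)  # superset
            c1 = classify_regulators(g1, ["K1", "K2"]).kinase_labels
            c2 = classify_regulators(g2, ["K1", "K2"]).kinase_labels
            for k in ("K1", "K2"):
                assert rank[c2[k]] >= rank[c1[k]]

    def test_matches_exhaustive_two_hop_enumeration(self):
        """500 random graphs (<= 50 nodes) vs. brute-force path search."""
        rng = np.random.default_rng(13)
        mrfs = list(DEFAULT_MRFS)
        for _ in range(500):
            n_other = int(rng.integers(3, 44))
            others = [f"N{i}" for i in range(n_other)]
            nodes = others + mrfs
            kinases = [f"K{i}" for i in range(int(rng.integers(1, 5)))]
            nodes = nodes + kinases
            p_edge = rng.uniform(0.02, 0.25)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < p_edge:
                    g.add_edge(a, b)
            cls = classify_regulators(g, kinases, mrfs)
            banned = set(kinases) | set(mrfs)
            for k in kinases:
                for m in mrfs:
                    if g.has_edge(k, m):
                        expected = "direct"
                    else:
                        # brute force: any length-2 path through a free node
                        mids = {
                            v for v in g.nodes
                            if v not in banned and g.has_edge(k, v) and g.has_edge(v, m)
                        }
                        expected = "semi_direct" if mids else "unconnected"
                    pc = cls.pairs[(k, m)]
                    assert pc.connection == expected
                    if expected == "semi_direct":
                        assert pc.intermediaries == frozenset(mids)


class TestSummarizeNetwork:
    def test_single_direct_pair(self):
        cls = classify_regulators(graph_from_edges([("K1", "MYF5")]), ["K1"])
        tables = summarize_network(cls)
        assert len(tables["kinases"]) == 1
        assert len(tables["mrfs"]) == 1
        assert len(tables["intermediaries"]) == 0

    def test_promiscuous_intermediary_tops_ranking(self):
        # E neighbors 4 MRFs and one kinase: links the kinase to 4 MRFs.
        edges = [("K1", "E")] + [("E", m) for m in ("MYOD1", "MEF2A", "MEF2C", "MEF2D")]
        edges += [("K1", "F"), ("F", "MYF5")]
        cls = classify_regulators(graph_from_edges(edges), ["K1"])
        inter = summarize_network(cls)["intermediaries"]
        assert inter.iloc[0].symbol == "E"
        assert inter.iloc[0].n_mrfs_linked == 4

    def test_ties_break_alphabetically(self):
        edges = [("KB", "X"), ("X", "MYOG"), ("KA", "Y"), ("Y", "MYOG")]
        cls = classify_regulators(graph_from_edges(edges), ["KA", "KB"])
        kin = summarize_network(cls)["kinases"]
        assert kin.symbol.tolist() == ["KA", "KB"]


class TestSifExport:
    def test_empty_classification_writes_empty_sif(self, tmp_path):
        cls = classify_regulators(nx.Graph(), ["K1"])
        sif = tmp_path / "net.sif"
        export_subnetwork(cls, nx.Graph(), sif)
        assert sif.read_text() == ""

    def test_direct_pair_single_line(self, tmp_path):
        graph = graph_from_edges([("CSNK2A2", "MYF5")])
        cls = classify_regulators(graph, ["CSNK2A2"])
        sif = tmp_path / "net.sif"
        attrs = tmp_path / "nodes.tsv"
        export_subnetwork(cls, graph, sif, attrs)
        assert sif.read_text() == "CSNK2A2\tdirect\tMYF5\n"
        assert "CSNK2A2\tkinase" in attrs.read_text()

    def test_sif_round_trip_reproduces_subgraph_edges(self, tmp_path):
        edges = [("K1", "X"), ("X", "MYOD1"), ("K2", "MYF5"), ("K1", "Y"),
                 ("Y", "MEF2A"), ("K9", "Z")]
        graph = graph_from_edges(edges)
        cls = classify_regulators(graph, ["K1", "K2", "K9"])
        sif = tmp_path / "net.sif"
        export_subnetwork(cls, graph, sif)
        back = read_sif(sif)
        expected = {("K1", "X"), ("MYOD1", "X"), ("K2", "MYF5"), ("K1", "Y"),
                    ("MEF2A", "Y")}
        assert {tuple(sorted(e)) for e in back.edges} == expected
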