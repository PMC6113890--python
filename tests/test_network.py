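"""Network assembly, motif detection vs brute force, exports, summaries."""

import itertools

import networkx as nx
import pandas as pd
import pytest
from lxml import etree

from efcascade.examples import cascade_example
from efcascade.network import (
    build_network,
    export_network,
    find_motifs,
    read_network_tsv,
    render_report,
    summarize,
)
from efcascade.regulation import call_regulation


def calls_table(rows):
    """rows: (tf, gene, mode)"""
    return pd.DataFrame(
        {
            "tf": [r[0] for r in rows],
            "gene_id": [r[1] for r in rows],
            "mode": [r[2] for r in rows],
            "log2fc": 1.0,
            "p_value": 0.01,
            "experiment": "MA1",
            "experiments_used": "MA1",
            "n_significant": 1,
            "sign_conflict": False,
            "note": "",
        }
    )


def cascade_graph():
    return build_network(
        calls_table(
            [
                ("Pax6", "Tbr2", "activates"),
                ("Tbr2", "Tbr1", "activates"),
                ("Tbr2", "Pax6", "represses"),
                ("Pax6", "Pax6", "represses"),
            ]
        )
    )


class TestBuildNetwork:
    def test_empty_calls_give_empty_network(self):
        g = build_network(calls_table([]))
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_cascade_fixture_counts(self):
        g = cascade_graph()
        assert g.number_of_edges() == 4
        assert g.number_of_nodes() == 3

    def test_non_edge_modes_are_skipped(self):
        g = build_network(
            calls_table(
                [("A", "x", "bound_no_de"), ("A", "y", "not_bound"), ("A", "z", "activates")]
            )
        )
        assert list(g.edges) == [("A", "z")]

    def test_synergy_expands_to_two_grouped_edges(self):
        g = build_network(calls_table([("Tbr1+Tbr2", "Chd3", "synergistic_activates")]))
        assert set(g.edges) == {("Tbr1", "Chd3"), ("Tbr2", "Chd3")}
        groups = {d["synergy_group"] for _, _, d in g.edges(data=True)}
        assert groups == {"Tbr1+Tbr2:Chd3"}
        assert all(d["sign"] == "+" for _, _, d in g.edges(data=True))

    def test_conflicting_duplicate_signs_raise(self):
        with pytest.raises(ValueError, match="conflicting signs"):
            build_network(
                calls_table([("A", "x", "activates"), ("A", "x", "represses")])
            )

    def test_roles_tag_tfs_even_when_also_targets(self):
        g = cascade_graph()
        assert g.nodes["Pax6"]["role"] == "TF"
        assert g.nodes["Tbr1"]["role"] == "EF"  # target only, default role

    def test_counts_match_reconstruction_on_random_tables(self, rng):
        modes = ["activates", "represses", "bound_no_de", "not_bound"]
        for _ in range(30):
            rows = [
                (f"T{int(rng.integers(3))}", f"g{int(rng.integers(10))}",
                 modes[int(rng.integers(len(modes)))])
                for _ in range(int(rng.integers(1, 20)))
            ]
            # deduplicate (tf, gene) keeping the first, as upstream guarantees
            seen, unique = set(), []
            for r in rows:
                if (r[0], r[1]) not in seen:
                    seen.add((r[0], r[1]))
                    unique.append(r)
            g = build_network(calls_table(unique))
            expect_edges = {(t, ge) for t, ge, m in unique if m in ("activates", "represses")}
            assert set(g.edges) == expect_edges


def brute_motifs(edges, tf_order):
    """Exhaustive oracle over a signed edge dict {(u, v): sign}."""
    pos = {tf: i for i, tf in enumerate(tf_order)}
    auto = sorted((u, s) for (u, v), s in edges.items() if u == v and u in pos)
    feedback = sorted(
        (u, v, s)
        for (u, v), s in edges.items()
        if u in pos and v in pos and pos[u] > pos[v]
    )
    valid = []
    for k in range(2, len(tf_order) + 1):
        for combo in itertools.combinations(tf_order, k):
            if all(edges.get((combo[i], combo[i + 1])) == "+" for i in range(k - 1)):
                valid.append(tuple(combo))
    maximal = [
        p
        for p in valid
        if not any(
            q != p
            and len(q) > len(p)
            and any(q[i : i + len(p)] == p for i in range(len(q) - len(p) + 1))
            for q in valid
        )
    ]
    return sorted(maximal), feedback, auto


def graph_from_edges(edges):
    g = nx.DiGraph()
    for (u, v), s in edges.items():
        g.add_edge(u, v, sign=s, synergy=False, synergy_group="", evidence="")
    return g


class TestFindMotifs:
    def test_cascade_fixture_motifs(self):
        report = find_motifs(cascade_graph(), ("Pax6", "Tbr2", "Tbr1"))
        assert report.feedforward_chains == [("Pax6", "Tbr2", "Tbr1")]
        assert report.feedback_edges == [("Tbr2", "Pax6", "-")]
        assert report.autoregulation == [("Pax6", "-")]

    def test_pure_positive_chain_has_no_feedback(self):
        g = build_network(
            calls_table([("A", "B", "activates"), ("B", "C", "activates")])
        )
        report = find_motifs(g, ("A", "B", "C"))
        assert report.feedback_edges == []
        assert report.autoregulation == []
        assert report.feedforward_chains == [("A", "B", "C")]

    def test_tf_missing_from_order_excluded_with_warning(self, caplog):
        g = build_network(calls_table([("A", "B", "activates"), ("X", "B", "activates")]))
        with caplog.at_level("WARNING"):
            report = find_motifs(g, ("A", "B"))
        assert "missing from tf_order" in caplog.text
        assert report.feedforward_chains == [("A", "B")]

    def test_exhaustive_on_all_3_node_signed_digraphs(self):
        order = ("A", "B", "C")
        pairs = [(u, v) for u in order for v in order]
        for assignment in itertools.product([None, "+", "-"], repeat=len(pairs)):
            edges = {
                pair: sign
                for pair, sign in zip(pairs, assignment)
                if sign is not None
            }
            got = find_motifs(graph_from_edges(edges), order)
            chains, feedback, auto = brute_motifs(edges, order)
            assert sorted(got.feedforward_chains) == chains
            assert sorted(got.feedback_edges) == feedback
            assert sorted(got.autoregulation) == auto

    def test_random_5_node_digraphs_match_brute_force(self, rng):
        order = ("A", "B", "C", "D", "E")
        pairs = [(u, v) for u in order for v in order]
        for _ in range(300):
            edges = {}
            for pair in pairs:
                u = rng.random()
                if u < 0.15:
                    edges[pair] = "+"
                elif u < 0.3:
                    edges[pair] = "-"
            got = find_motifs(graph_from_edges(edges), order)
            chains, feedback, auto = brute_motifs(edges, order)
            assert sorted(got.feedforward_chains) == chains
            assert sorted(got.feedback_edges) == feedback
            assert sorted(got.autoregulation) == auto


class TestSummarize:
    def test_per_tf_counts(self):
        g = build_network(
            calls_table(
                [
                    ("A", "x", "activates"),
                    ("A", "y", "activates"),
                    ("A", "z", "represses"),
                ]
            )
        )
        s = summarize(g)
        assert s["per_tf"]["A"] == {"activated": 2, "repressed": 1, "synergistic": 0}
        # conservation: tallies equal qualifying edge count
        assert sum(sum(c.values()) for c in s["per_tf"].values()) == s["n_edges"]

    def test_union_counts_each_gene_once(self):
        g = build_network(calls_table([("A", "gene1", "activates")]))
        celltypes = pd.DataFrame({"gene_id": ["gene1", "gene2"], "label": ["RGP", "none"]})
        grads = pd.DataFrame({"gene_id": ["gene1"], "direction": ["high_caudal"]})
        s = summarize(g, celltypes, grads)
        assert s["n_celltype_specific"] == 1
        assert s["n_graded"] == 1
        assert s["n_regulated"] == 1
        assert s["n_union"] == 1  # same gene in all three categories

    def test_synergy_counted_as_separate_tally(self):
        g = build_network(calls_table([("Tbr1+Tbr2", "Chd3", "synergistic_activates")]))
        s = summarize(g)
        assert s["synergy_pairs"] == {"Tbr1+Tbr2": 1}
        assert s["per_tf"]["Tbr1"]["synergistic"] == 1
        assert s["per_tf"]["Tbr2"]["synergistic"] == 1
        assert "synergistically regulate 1" in render_report(s)


class TestExport:
    def test_sif_is_four_lines_for_cascade(self, tmp_path):
        path = export_network(cascade_graph(), tmp_path / "net.sif", "sif")
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 4
        assert "Pax6\tactivates\tTbr2" in lines
        assert "Tbr2\trepresses\tPax6" in lines

    def test_tsv_round_trip_is_lossless(self, tmp_path):
        g = cascade_graph()
        path = export_network(g, tmp_path / "net.tsv", "tsv")
        back = read_network_tsv(path)
        assert set(back.edges) == set(g.edges)
        for u, v in g.edges:
            assert back.edges[u, v]["sign"] == g.edges[u, v]["sign"]
            assert back.edges[u, v]["synergy"] == g.edges[u, v]["synergy"]

    def test_graphml_is_well_formed_with_attributes(self, tmp_path):
        path = export_network(cascade_graph(), tmp_path / "net.graphml", "graphml")
        tree = etree.parse(str(path))
        assert tree.getroot().tag.endswith("graphml")
        back = nx.read_graphml(path)
        assert back.number_of_edges() == 4
        assert back.edges["Pax6", "Tbr2"]["sign"] == "+"

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown export format"):
            export_network(cascade_graph(), tmp_path / "x", "xlsx")


def test_cascade_example_end_to_end():
    """The worked TF-trio dataset assembles into the published wiring."""
    ex = cascade_example()
    calls = call_regulation(ex["binding"], ex["summaries"], exclusions=ex["exclusions"])
    g = build_network(calls)
    assert dict(((u, v), d["sign"]) for u, v, d in g.edges(data=True)) == {
        ("Pax6", "Tbr2"): "+",
        ("Tbr2", "Tbr1"): "+",
        ("Tbr2", "Pax6"): "-",
        ("Pax6", "Pax6"): "-",
    }
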