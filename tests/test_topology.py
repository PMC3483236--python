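import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comboreg.topology import (MotifType, betweenness, coordinating_pairs,
                               degree_statistics, enumerate_motif_types,
                               krackhardt_hierarchy, motif_census,
                               motif_significance, out_degree_powerlaw_fit,
                               randomize_network)

from conftest import random_digraph
from oracles import (brute_betweenness, brute_fisher_greater,
                     brute_krackhardt, brute_motif_counts)


def signed_graph(edges, kinds):
    """Build a DiGraph with node kinds and signed edges.

    ``edges`` is a list of (u, v, sign); ``kinds`` maps node -> kind.
    """
    g = nx.DiGraph()
    for v, kind in kinds.items():
        g.add_node(v, kind={"miR": "miRNA"}.get(kind, kind))
    for u, v, s in edges:
        g.add_edge(u, v, efficacy=float(s),
                   sign="activating" if s > 0 else "repressing")
    return g


class TestDegreeStatistics:
    def test_out_star(self):
        g = nx.DiGraph([("hub", f"leaf{i}") for i in range(5)])
        table, _ = degree_statistics(g)
        row = table.set_index("vertex").loc["hub"]
        assert (row.out_degree, row.in_degree) == (5, 0)

    def test_hand_counted_toy_graph(self):
        g = nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"),
                        ("d", "a"), ("e", "f")])
        table, corr = degree_statistics(g)
        t = table.set_index("vertex")
        assert t.loc["a", "out_degree"] == 2 and t.loc["a", "in_degree"] == 1
        assert t.loc["c", "in_degree"] == 2 and t.loc["f", "out_degree"] == 0
        expected = stats.pearsonr(t.in_degree, t.out_degree).statistic
        assert corr == pytest.approx(expected)

    def test_correlation_na_for_degenerate_graph(self):
        _, corr = degree_statistics(nx.DiGraph([("a", "b")]))
        assert np.isnan(corr)


class TestPowerlawFit:
    def test_exact_recovery_of_planted_slope(self):
        # out-degree frequencies following f(k) = C * k^(-0.5) exactly
        g = nx.DiGraph()
        node = 0
        for k in (1, 4, 16, 64):
            n_k = 64 // int(np.sqrt(k))  # exact: 64, 32, 16, 8
            for _ in range(n_k):
                hub = f"h{node}"
                for j in range(k):
                    g.add_edge(hub, f"t{node}_{j}")
                node += 1
        slope, p = out_degree_powerlaw_fit(g)
        assert slope == pytest.approx(-0.5, abs=1e-9)
        assert p < 0.01

    def test_single_degree_value_gives_na(self):
        g = nx.DiGraph([("a", "b"), ("c", "d")])
        slope, p = out_degree_powerlaw_fit(g)
        assert np.isnan(slope) and np.isnan(p)


class TestBetweenness:
    def test_two_hop_path(self):
        scores = betweenness(nx.DiGraph([("a", "b"), ("b", "c")]))
        assert scores == {"a": 0, "b": 1, "c": 0}

    def test_disconnected_vertex_is_zero(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        g.add_node("island")
        assert betweenness(g)["island"] == 0

    def test_matches_path_enumeration_oracle_on_random_digraphs(self):
        rng = np.random.default_rng(10)
        for n in (4, 5, 6):
            for _ in range(8):
                g = random_digraph(rng, n, p=0.35)
                fast = betweenness(g)
                slow = brute_betweenness(list(g.nodes), list(g.edges))
                for v in g.nodes:
                    assert fast[v] == pytest.approx(slow[v], abs=1e-12)


class TestKrackhardtHierarchy:
    def test_dag_scores_one(self):
        g = nx.gn_graph(12, seed=1).reverse()
        assert krackhardt_hierarchy(g) == 1.0

    def test_two_cycle_scores_zero(self):
        assert krackhardt_hierarchy(nx.DiGraph([("a", "b"), ("b", "a")])) == 0.0

    def test_edgeless_network_is_na(self):
        g = nx.DiGraph()
        g.add_nodes_from("abc")
        assert np.isnan(krackhardt_hierarchy(g))

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            g = random_digraph(rng, 8, p=0.25)
            assert krackhardt_hierarchy(g) == pytest.approx(
                brute_krackhardt(list(g.nodes), list(g.edges)), abs=1e-12)


class TestCoordinatingPairs:
    def test_full_overlap_in_large_universe_is_significant(self):
        kinds = {"A": "TF", "B": "TF"}
        edges = []
        for t in range(10):
            kinds[f"g{t}"] = "gene"
            edges += [("A", f"g{t}", 1), ("B", f"g{t}", 1)]
        # pad the target universe to 1000 distinct genes
        kinds["C"] = "TF"
        for t in range(10, 1000):
            kinds[f"g{t}"] = "gene"
            edges.append(("C", f"g{t}", 1))
        out = coordinating_pairs(signed_graph(edges, kinds))
        ab = out[(out.regulator_a == "A") & (out.regulator_b == "B")]
        assert len(ab) == 1 and ab.p_value.iloc[0] < 1e-10
        assert ab.group.iloc[0] == "TF-TF"

    def test_disjoint_target_sets_not_reported(self):
        kinds = {"A": "TF", "B": "miR", "g1": "gene", "g2": "gene"}
        out = coordinating_pairs(
            signed_graph([("A", "g1", 1), ("B", "g2", -1)], kinds))
        assert out.empty

    def test_fisher_p_matches_fixed_margin_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 13, size=4)
            if (a + b) == 0 or (a + c) == 0:
                continue
            table = [[int(a), int(b)], [int(c), int(d)]]
            assert stats.fisher_exact(table, alternative="greater")[1] == \
                pytest.approx(brute_fisher_greater(table), abs=1e-12)


class TestMotifEnumeration:
    def test_exactly_fourteen_ffl_and_four_fbl_types(self):
        types = enumerate_motif_types()
        assert len(types) == 18
        assert sum(t.skeleton == "FFL" for t in types) == 14
        assert sum(t.skeleton == "FBL" for t in types) == 4

    def test_every_type_is_legal_and_mixed(self):
        legal = {("TF", "gene"), ("TF", "TF"), ("TF", "miR"),
                 ("miR", "gene"), ("miR", "TF")}
        for t in enumerate_motif_types():
            assert "TF" in t.kinds and "miR" in t.kinds
            arcs = ([(0, 1), (1, 2), (0, 2)] if t.skeleton == "FFL"
                    else [(0, 1), (1, 2), (2, 0)])
            for (i, j), sign in zip(arcs, t.signs):
                assert (t.kinds[i], t.kinds[j]) in legal
                if t.kinds[i] == "miR":
                    assert sign == -1  # miRNA edges always repress

    def test_brute_force_triad_generation_reproduces_the_set(self):
        """Independently enumerate all signed typed triads under the rules
        and compare with the package's catalogue."""
        legal = {("TF", "gene"), ("TF", "TF"), ("TF", "miR"),
                 ("miR", "gene"), ("miR", "TF")}
        sign_choices = lambda k: [1, -1] if k == "TF" else [-1]
        expected = set()
        for kinds in itertools.product(("TF", "miR", "gene"), repeat=3):
            if "TF" not in kinds or "miR" not in kinds:
                continue
            a, b, c = kinds
            if c != "TF" and all(e in legal for e in [(a, b), (b, c), (a, c)]):
                for s in itertools.product(sign_choices(a), sign_choices(b),
                                           sign_choices(a)):
                    expected.add(("FFL", kinds, s))
            if all(e in legal for e in [(a, b), (b, c), (c, a)]):
                for s in itertools.product(sign_choices(a), sign_choices(b),
                                           sign_choices(c)):
                    # canonical rotation: miRNA first
                    rot = [(kinds[i:] + kinds[:i], s[i:] + s[:i])
                           for i in range(3)]
                    k2, s2 = next((k, sg) for k, sg in rot if k[0] == "miR")
                    expected.add(("FBL", k2, s2))
        got = {(t.skeleton, t.kinds, t.signs) for t in enumerate_motif_types()}
        assert got == expected


class TestMotifCensus:
    def test_single_instance_counted_once(self):
        kinds = {"m": "miR", "t": "TF", "g": "gene"}
        g = signed_graph([("m", "t", -1), ("t", "g", 1), ("m", "g", -1)], kinds)
        census = motif_census(g)
        assert census["count"].sum() == 1
        (hit,) = census[census["count"] == 1].motif
        assert hit == "FFL:miR--->TF-+->gene|miR--->gene"

    def test_empty_network_all_zero(self):
        census = motif_census(nx.DiGraph())
        assert len(census) == 18 and (census["count"] == 0).all()

    def test_matches_brute_force_triple_scan(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            kinds, edges = _random_signed_network(rng, n=30, n_edges=70)
            g = signed_graph(edges, kinds)
            fast = dict(zip(motif_census(g).motif, motif_census(g)["count"]))
            slow = brute_motif_counts(
                list(kinds), kinds, {(u, v): s for u, v, s in edges})
            for label, count in fast.items():
                assert count == slow.get(label, 0)

    def test_invariant_under_vertex_relabeling(self):
        rng = np.random.default_rng(14)
        kinds, edges = _random_signed_network(rng, n=20, n_edges=45)
        g = signed_graph(edges, kinds)
        base = motif_census(g).set_index("motif")["count"]
        mapping = dict(zip(sorted(kinds), rng.permutation(sorted(kinds))))
        relabeled = signed_graph(
            [(mapping[u], mapping[v], s) for u, v, s in edges],
            {mapping[v]: k for v, k in kinds.items()})
        pd.testing.assert_series_equal(
            base, motif_census(relabeled).set_index("motif")["count"])


def _random_signed_network(rng, n=30, n_edges=60):
    """Random kind-legal signed digraph for census cross-checks."""
    kinds = {}
    for i in range(n):
        kinds[f"v{i}"] = ("TF", "miR", "gene")[rng.integers(3)]
    legal = {("TF", "gene"), ("TF", "TF"), ("TF", "miR"),
             ("miR", "gene"), ("miR", "TF")}
    edges = {}
    nodes = list(kinds)
    tries = 0
    while len(edges) < n_edges and tries < 50 * n_edges:
        tries += 1
        u, v = rng.choice(nodes, 2, replace=False)
        if (kinds[u], kinds[v]) not in legal or (u, v) in edges:
            continue
        sign = -1 if kinds[u] == "miR" else (1 if rng.random() < 0.5 else -1)
        edges[(u, v)] = sign
    return kinds, [(u, v, s) for (u, v), s in edges.items()]


class TestRandomization:
    def test_per_type_degrees_and_signs_preserved(self):
        rng_net = np.random.default_rng(15)
        kinds, edges = _random_signed_network(rng_net, n=25, n_edges=60)
        g = signed_graph(edges, kinds)
        shuffled = randomize_network(g, np.random.default_rng(0))

        def profile(graph):
            per_vertex = {}
            for v in graph:
                tgt_kind = lambda w: ("miR" if graph.nodes[w]["kind"] == "miRNA"
                                      else "mRNA")
                outs = sorted(tgt_kind(w) for w in graph.successors(v))
                ins = sorted(tgt_kind(v) for _ in graph.predecessors(v))
                signs = sorted(np.sign(graph.edges[v, w]["efficacy"])
                               for w in graph.successors(v))
                per_vertex[v] = (outs, len(list(graph.predecessors(v))), signs)
            return per_vertex

        assert g.number_of_edges() == shuffled.number_of_edges()
        assert profile(g) == profile(shuffled)

    def test_shuffling_actually_moves_edges(self):
        rng_net = np.random.default_rng(16)
        kinds, edges = _random_signed_network(rng_net, n=25, n_edges=60)
        g = signed_graph(edges, kinds)
        shuffled = randomize_network(g, np.random.default_rng(1))
        assert set(g.edges) != set(shuffled.edges)


class TestMotifSignificance:
    def test_zero_observed_count_gives_p_one(self):
        kinds = {"m": "miR", "t": "TF", "g": "gene"}
        g = signed_graph([("t", "g", 1)], kinds)
        out = motif_significance(g, n_rand=10, seed=0)
        assert (out.loc[out["count"] == 0, "p_value"] == 1.0).all()

    def test_planted_motif_detected(self):
        """A motif planted far above chance is flagged at p < 0.01 with 200
        degree-preserving randomizations."""
        rng = np.random.default_rng(17)
        kinds, edges = {}, []
        # 30 disjoint instances of miR -| TF -> gene, miR -| gene
        for i in range(30):
            m, t, g = f"m{i}", f"t{i}", f"g{i}"
            kinds.update({m: "miR", t: "TF", g: "gene"})
            edges += [(m, t, -1), (t, g, 1), (m, g, -1)]
        # sparse background so randomization has room to destroy triangles
        for i in range(60):
            kinds[f"x{i}"] = "gene"
            edges.append((f"t{i % 30}", f"x{i}", 1))
            edges.append((f"m{(i * 7) % 30}", f"x{(i * 3) % 60}", -1))
        g = signed_graph(edges, kinds)
        out = motif_significance(g, n_rand=200, seed=3)
        target = "FFL:miR--->TF-+->gene|miR--->gene"
        row = out[out.motif == target].iloc[0]
        assert row["count"] >= 30
        assert row.p_value < 0.01
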