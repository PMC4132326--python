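"""Graphs, cliques, isomorphic matching, skeleton networks, queries."""

import itertools

import networkx as nx
import numpy as np
import pytest

import pcopnet as pn
from pcopnet.networks import GeneClique

from conftest import brute_force_bijections, brute_force_maximal_cliques


def rel(a, b, klass, ctype="LIN_POS", f=0.01):
    return pn.PairRelationship(*sorted((a, b)), f, 0 if klass == "linear" else 1,
                               ctype, klass, "")


def clique(genes, types):
    """types: dict of unordered pairs -> canonical curve type."""
    return GeneClique(tuple(sorted(genes)),
                      {frozenset(k): v for k, v in types.items()})


class TestBuildGraphs:
    def test_edge_partition(self):
        table = [rel("A", "B", "linear"), rel("A", "C", "linear"),
                 rel("B", "C", "nonlinear", "EXP_POS"),
                 rel("C", "D", "rejected", "COMPLEX", 0.9)]
        co, nl = pn.build_graphs(table)
        assert co.number_of_edges() == 2
        assert nl.number_of_edges() == 1
        assert nl.edges["B", "C"]["curve_type"] == "EXP_POS"
        assert not set(co.edges) & set(nl.edges)

    def test_empty_table_gives_empty_graphs(self):
        co, nl = pn.build_graphs([])
        assert co.number_of_edges() == nl.number_of_edges() == 0


class TestCliqueEnumeration:
    def test_triangle_is_one_clique(self):
        table = [rel("A", "B", "nonlinear", "EXP_POS"),
                 rel("A", "C", "nonlinear", "EXP_POS"),
                 rel("B", "C", "nonlinear", "EXP_POS")]
        _, nl = pn.build_graphs(table)
        cliques = pn.enumerate_gene_cliques(nl)
        assert len(cliques) == 1 and cliques[0].genes == ("A", "B", "C")

    def test_edgeless_graph_yields_nothing(self):
        g = nx.Graph()
        g.add_nodes_from("ABCD")
        assert pn.enumerate_gene_cliques(g) == []

    def test_agrees_with_brute_force_on_random_graphs(self):
        """Maximal cliques equal exhaustive subset enumeration, 30 seeded graphs."""
        for seed in range(30):
            g = nx.erdos_renyi_graph(12, 0.5, seed=seed)
            g = nx.relabel_nodes(g, {i: f"G{i:02d}" for i in g.nodes})
            nx.set_edge_attributes(g, "COMPLEX", "curve_type")
            ours = {frozenset(c.genes) for c in pn.enumerate_gene_cliques(g, min_size=3)}
            oracle = {c for c in brute_force_maximal_cliques(g) if len(c) >= 3}
            assert ours == oracle

    def test_deterministic_order(self):
        g = nx.erdos_renyi_graph(10, 0.6, seed=4)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        nx.set_edge_attributes(g, "COMPLEX", "curve_type")
        a = [c.genes for c in pn.enumerate_gene_cliques(g)]
        b = [c.genes for c in pn.enumerate_gene_cliques(g)]
        assert a == b == sorted(a)


def coexpr_graph(edges):
    g = nx.Graph()
    for a, b in edges:
        g.add_edge(a, b, f=0.01)
    return g


class TestIsomorphicMatching:
    def planted_pair(self):
        c1 = clique(["A1", "A2", "A3"], {("A1", "A2"): "EXP_POS",
                                         ("A1", "A3"): "EXP_POS",
                                         ("A2", "A3"): "LOG_NEG"})
        c2 = clique(["B1", "B2", "B3"], {("B1", "B2"): "EXP_POS",
                                         ("B1", "B3"): "EXP_POS",
                                         ("B2", "B3"): "LOG_NEG"})
        co = coexpr_graph([("A1", "B1"), ("A2", "B2"), ("A3", "B3")])
        return c1, c2, co

    def test_unique_planted_mapping_found(self):
        c1, c2, co = self.planted_pair()
        bij = pn.match_isomorphic_pair(c1, c2, co)
        oracle = brute_force_bijections(c1, c2, co)
        assert len(oracle) == 1
        assert bij == oracle[0] == {"A1": "B1", "A2": "B2", "A3": "B3"}

    def test_size_mismatch_returns_none(self):
        c1, c2, co = self.planted_pair()
        c3 = clique(["B1", "B2", "B3", "B4"],
                    {p: "EXP_POS" for p in itertools.combinations(
                        ["B1", "B2", "B3", "B4"], 2)})
        assert pn.match_isomorphic_pair(c1, c3, co) is None

    def test_type_mismatch_returns_none(self):
        c1, c2, co = self.planted_pair()
        bad = clique(["B1", "B2", "B3"], {("B1", "B2"): "EXP_POS",
                                          ("B1", "B3"): "EXP_POS",
                                          ("B2", "B3"): "QUAD_POS"})
        assert pn.match_isomorphic_pair(c1, bad, co) is None

    def test_agrees_with_permutation_oracle_on_random_pairs(self):
        """Matcher verdict equals exhaustive permutation search, 50 seeded pairs."""
        types = ["EXP_POS", "LOG_NEG", "QUAD_POS", "COMPLEX"]
        for seed in range(50):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(3, 7))
            g1 = [f"A{i}" for i in range(k)]
            g2 = [f"B{i}" for i in range(k)]
            t1 = {p: types[rng.integers(len(types))]
                  for p in itertools.combinations(g1, 2)}
            if rng.random() < 0.5:
                # planted isomorphic partner under a random bijection
                perm = rng.permutation(k)
                mapping = {g1[i]: g2[perm[i]] for i in range(k)}
                t2 = {}
                for (a, b), t in t1.items():
                    x, y = mapping[a], mapping[b]
                    t2[(x, y)] = t if (x < y) == (a < b) else pn.transpose_type(t)
            else:
                t2 = {p: types[rng.integers(len(types))]
                      for p in itertools.combinations(g2, 2)}
            edges = [(a, b) for a in g1 for b in g2 if rng.random() < 0.7]
            co = coexpr_graph(edges) if edges else nx.Graph()
            c1, c2 = clique(g1, t1), clique(g2, t2)
            got = pn.match_isomorphic_pair(c1, c2, co)
            oracle = brute_force_bijections(c1, c2, co)
            if oracle:
                assert got in oracle
            else:
                assert got is None


def triple_planted():
    """Three pairwise-matched triangles (one gene per process each)."""
    tri = {("1", "2"): "EXP_POS", ("1", "3"): "LOG_NEG", ("2", "3"): "LOG_NEG"}
    cliques = []
    for p in "ABC":
        genes = [f"{p}{i}" for i in (1, 2, 3)]
        types = {}
        for (i, j), t in tri.items():
            a, b = f"{p}{i}", f"{p}{j}"
            types[(a, b)] = t if (a < b) else pn.transpose_type(t)
        cliques.append(clique(genes, types))
    co = coexpr_graph([(f"{p}{i}", f"{q}{i}")
                       for p, q in itertools.combinations("ABC", 2)
                       for i in (1, 2, 3)])
    pairs = pn.match_all_pairs(cliques, co)
    return cliques, pairs, co


class TestCliquesOfCliques:
    def test_three_matched_cliques_form_one_network(self):
        cliques, pairs, _ = triple_planted()
        assert len(pairs) == 3
        nets = pn.cliques_of_cliques(cliques, pairs)
        assert len(nets) == 1
        net = nets[0]
        assert net.n_sets == 3
        # sets are the transversal coexpression groups, one gene per clique
        skels = sorted(s.skeleton for s in net.sets)
        assert skels == [("A1", "B1", "C1"), ("A2", "B2", "C2"), ("A3", "B3", "C3")]
        assert net.signature() == (3, ("EXP_POS", "LOG_NEG", "LOG_NEG"))

    def test_two_matched_cliques_are_not_enough(self):
        cliques, pairs, _ = triple_planted()
        two = [p for p in pairs if {p.clique_a, p.clique_b} == {0, 1}]
        assert pn.cliques_of_cliques(cliques[:2], two) == []

    def test_every_network_is_complete(self, planted_networks):
        _, _, result = planted_networks
        for net in result.networks:
            for i, j in itertools.combinations(range(net.n_sets), 2):
                assert frozenset((i, j)) in net.intergroup_types


class TestHalo:
    def test_no_linear_neighbours_means_empty_halo(self):
        cliques, pairs, _ = triple_planted()
        co = nx.Graph()
        nets = pn.cliques_of_cliques(cliques, pairs)
        pn.attach_halo(nets[0], co, [])
        assert all(s.halo == [] for s in nets[0].sets)

    def test_halo_sorted_by_f_with_best_anchor(self):
        cliques, pairs, co = triple_planted()
        co.add_edge("A1", "H1", f=0.05)
        co.add_edge("B1", "H1", f=0.02)
        co.add_edge("A1", "H2", f=0.01)
        nets = pn.cliques_of_cliques(cliques, pairs)
        pn.attach_halo(nets[0], co, [])
        set1 = next(s for s in nets[0].sets if "A1" in s.skeleton)
        assert [h[0] for h in set1.halo] == ["H2", "H1"]
        assert set1.halo[1] == ("H1", 0.02, "B1")
        fs = [h[1] for h in set1.halo]
        assert fs == sorted(fs)


class TestSignature:
    def test_uniform_type_signature(self):
        s = pn.SkeletonNetwork(
            sets=[pn.CoexpressedSet(("A",)), pn.CoexpressedSet(("B",)),
                  pn.CoexpressedSet(("C",))],
            intergroup_types={frozenset((0, 1)): "EXP_POS",
                              frozenset((0, 2)): "EXP_POS",
                              frozenset((1, 2)): "EXP_POS"})
        assert pn.network_signature(s) == (3, ("EXP_POS", "EXP_POS", "EXP_POS"))

    def test_relabeling_sets_preserves_signature(self):
        types = {frozenset((0, 1)): "EXP_POS", frozenset((0, 2)): "LOG_NEG",
                 frozenset((1, 2)): "QUAD_POS"}
        a = pn.SkeletonNetwork([pn.CoexpressedSet((g,)) for g in "XYZ"], types)
        perm = {0: 2, 1: 0, 2: 1}
        types_p = {}
        for k, t in types.items():
            i, j = sorted(k)
            mi, mj = perm[i], perm[j]
            types_p[frozenset((mi, mj))] = t if (mi < mj) else pn.transpose_type(t)
        b = pn.SkeletonNetwork([pn.CoexpressedSet((g,)) for g in "ZXY"], types_p)
        assert pn.network_signature(a) == pn.network_signature(b)


class TestQueryGene:
    def table(self):
        return [
            rel("A", "B", "linear", f=0.02),
            rel("A", "C", "linear", f=0.01),
            rel("B", "C", "linear", f=0.03),
            rel("A", "X", "nonlinear", "EXP_POS", f=0.05),
            rel("X", "Y", "linear", f=0.02),
            rel("D", "E", "rejected", "COMPLEX", f=0.8),
        ]

    def test_gene_without_nonlinear_partners(self):
        assert pn.query_gene(self.table(), "B") == []

    def test_unknown_gene_raises(self):
        with pytest.raises(pn.UnknownGeneError):
            pn.query_gene(self.table(), "ZZ")

    def test_entry_lists_and_ordering(self):
        entries = pn.query_gene(self.table(), "A")
        assert len(entries) == 1
        e = entries[0]
        assert e["partner"] == "X" and e["curve_type"] == "EXP_POS"
        own = [d["gene"] for d in e["gene_coexpressed"]]
        assert own == ["C", "B"]  # ascending f: 0.01 then 0.02
        assert [d["gene"] for d in e["partner_coexpressed"]] == ["Y"]
        fs = [d["f"] for d in e["gene_coexpressed"]]
        assert fs == sorted(fs)

    def test_orientation_follows_query_gene(self):
        entries = pn.query_gene(self.table(), "X")
        # stored as (A, X) EXP_POS with A on x; seen from X it transposes
        assert entries[0]["curve_type"] == "LOG_POS"
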