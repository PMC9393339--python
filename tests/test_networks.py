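import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncfat.cis_targets import CisTargetLink
from lncfat.coexpression import CoexpressionPair
from lncfat.networks import (
    assemble_tripartite,
    build_subnetwork,
    hypergeom_enrich,
    identify_tfs,
    radiality,
)
from oracles import brute_radiality, exact_hypergeom_tail


def edge_frame(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


class TestBuildSubnetwork:
    def test_threshold_and_induction(self):
        edges = edge_frame([
            ("a", "b", 0.69),   # below threshold
            ("a", "c", 0.70),   # boundary: inclusive
            ("c", "d", 0.95),   # d not a seed
            ("b", "c", 0.80),
            ("c", "c", 0.99),   # self-loop
        ])
        g = build_subnetwork(edges, {"a", "b", "c"})
        assert {frozenset(e) for e in g.edges} == {
            frozenset({"a", "c"}), frozenset({"b", "c"})}
        assert g["a"]["c"]["score"] == 0.70

    def test_duplicate_edges_keep_max_score(self):
        edges = edge_frame([("a", "b", 0.75), ("b", "a", 0.9)])
        g = build_subnetwork(edges, {"a", "b"})
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["score"] == 0.9

    def test_empty_result_warns(self, caplog):
        with caplog.at_level("WARNING", logger="lncfat.networks"):
            g = build_subnetwork(edge_frame([("a", "b", 0.2)]), {"a", "b"})
        assert g.number_of_edges() == 0
        assert "threshold" in caplog.text

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            build_subnetwork(edge_frame([("a", "b", 1.2)]), {"a", "b"})


class TestRadiality:
    def test_complete_graph_all_one(self):
        g = nx.complete_graph(4)
        res = radiality(nx.relabel_nodes(g, str))
        assert all(r.crad == pytest.approx(1.0) for r in res)

    def test_path_graph(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        crad = {r.node: r.crad for r in radiality(g)}
        # diameter 2: b sums (2+1-1)*2 -> 4/2 = 2; a sums (2)+(1) -> 3/2
        assert crad == {"a": 1.5, "b": 2.0, "c": 1.5}

    def test_two_disjoint_edges(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        res = radiality(g)
        assert [r.node for r in res] == ["a", "b", "c", "d"]  # tie-break by id
        assert [r.rank for r in res] == [1, 2, 3, 4]
        assert all(r.crad == pytest.approx(1.0) for r in res)
        assert len({r.component for r in res}) == 2

    def test_singleton_component_zero(self):
        g = nx.Graph([("a", "b")])
        g.add_node("lonely")
        crad = {r.node: r.crad for r in radiality(g)}
        assert crad["lonely"] == 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            radiality(nx.Graph())

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 50),
           p=st.floats(0.05, 0.6))
    def test_matches_brute_force_oracle(self, seed, n, p):
        g = nx.gnp_random_graph(n, p, seed=seed)
        g = nx.relabel_nodes(g, lambda v: f"n{v:02d}")
        want = brute_radiality(list(g.edges), list(g.nodes))
        got = {r.node: r.crad for r in radiality(g)}
        assert got.keys() == want.keys()
        for v in want:
            assert got[v] == pytest.approx(want[v], abs=1e-12)

    def test_relabel_invariance(self):
        g = nx.gnp_random_graph(20, 0.2, seed=3)
        g1 = nx.relabel_nodes(g, lambda v: f"a{v}")
        g2 = nx.relabel_nodes(g, lambda v: f"z{19 - v}")
        c1 = sorted(r.crad for r in radiality(g1))
        c2 = sorted(r.crad for r in radiality(g2))
        assert c1 == pytest.approx(c2)


class TestTfIdentification:
    def test_lookup_and_fd_flag(self):
        table = {"tf1": "bZIP", "tf2": "MYB"}
        recs = identify_tfs({"tf1", "tf2", "plain"}, table, fd_degs={"tf1"})
        by_id = {r.gene_id: r for r in recs}
        assert set(by_id) == {"tf1", "tf2"}
        assert by_id["tf1"].is_fd_detf and not by_id["tf2"].is_fd_detf
        assert by_id["tf2"].family == "MYB"

    def test_planted_tfs_found(self, small_dataset):
        ds = small_dataset
        genes = set(ds.tf_table) | {"unrelated"}
        recs = identify_tfs(genes, ds.tf_table, fd_degs=ds.truth.planted_tfs)
        assert {r.gene_id for r in recs} == set(ds.tf_table)
        assert {r.gene_id for r in recs if r.is_fd_detf} == ds.truth.planted_tfs


class TestTripartite:
    def test_counting_example(self):
        cis = [CisTargetLink("l1", "tf1", 100, "upstream"),
               CisTargetLink("l2", "tf1", 0, "overlapping")]
        pairs = [CoexpressionPair("tf1", f"g{i}", 0.9, 6) for i in range(3)]
        tri = assemble_tripartite({"tf1"}, cis, pairs)
        assert (len(tri.tf_nodes), len(tri.lncrna_nodes), len(tri.gene_nodes)) == (1, 2, 3)
        assert tri.graph.number_of_edges() == 5
        assert tri.tf_in_degree()["tf1"] == 2
        assert tri.tf_out_degree()["tf1"] == 3

    def test_isolated_tf_excluded(self):
        tri = assemble_tripartite({"tf1", "tf2"},
                                  [CisTargetLink("l1", "tf1", 0, "overlapping")],
                                  [])
        assert tri.tf_nodes == {"tf1"}

    def test_max_out_degree_tf_tops_ranking(self):
        pairs = ([CoexpressionPair("big", f"g{i}", 0.9, 6) for i in range(4)]
                 + [CoexpressionPair("small", "g0", 0.9, 6)])
        tri = assemble_tripartite({"big", "small"}, [], pairs)
        assert tri.tf_out_degree().index[0] == "big"


class TestEnrichment:
    def universe(self, n):
        return {f"g{i}" for i in range(n)}

    def term_table(self, terms):
        return pd.DataFrame(
            [(t, g) for t, genes in terms.items() for g in genes],
            columns=["term_id", "gene_id"],
        )

    def test_selected_equals_universe_p_one(self):
        uni = self.universe(10)
        tt = self.term_table({"T1": list(uni)[:5], "T2": list(uni)[2:8]})
        res = hypergeom_enrich(uni, uni, tt)
        assert np.allclose(res["pvalue"], 1.0)

    def test_exact_small_case(self):
        uni = self.universe(10)
        tt = self.term_table({"T1": [f"g{i}" for i in range(5)]})
        res = hypergeom_enrich({"g0", "g1", "g2"}, uni, tt)
        assert res.loc[0, "pvalue"] == pytest.approx(10 / 120, abs=1e-12)

    def test_empty_term_overlap(self):
        uni = self.universe(10)
        tt = self.term_table({"T1": ["g0", "g1"]})
        res = hypergeom_enrich({"g8", "g9"}, uni, tt)
        assert res.loc[0, "fold_enrichment"] == 0.0
        assert res.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="alien"):
            hypergeom_enrich({"alien"}, self.universe(5),
                             self.term_table({"T": ["g0"]}))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(m=st.integers(2, 20), data=st.data())
    def test_matches_exact_enumeration(self, m, data):
        """Tail p-values agree with exact rational enumeration (<= 1e-10)."""
        uni = sorted(self.universe(m))
        k_term = data.draw(st.integers(1, m))
        n_sel = data.draw(st.integers(1, m))
        term = uni[:k_term]
        sel = set(data.draw(st.permutations(uni))[:n_sel])
        res = hypergeom_enrich(sel, set(uni), self.term_table({"T": term}))
        k = len(set(term) & sel)
        want = float(exact_hypergeom_tail(k, m, k_term, n_sel))
        assert res.loc[0, "pvalue"] == pytest.approx(want, abs=1e-10)
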