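import numpy as np
import pandas as pd
import pytest

from triadnet import expression_io as eio, grn_assembly as grn, importance_scoring as sc


def small_net():
    net = grn.MixedNetwork()
    for n in ("tf1", "g2", "g3"):
        net.add_node(n, is_tf=(n == "tf1"))
    net.add_regulation("tf1", "g2", "tf_regulation")
    net.add_regulation("tf1", "g3", "tf_regulation")
    net.add_coexpression("g2", "g3", 0.73)
    return net


def expression_for(nodes, values_by_node):
    samples, meta_rows = [], []
    for cond in ("A", "B"):
        for rep in (1, 2):
            sid = f"{cond}_lung_{rep}"
            samples.append(sid)
            meta_rows.append(
                {"sample_id": sid, "condition": cond, "tissue": "lung", "replicate": rep}
            )
    vals = pd.DataFrame(
        {s: [values_by_node[n][i] for n in nodes] for i, s in enumerate(samples)},
        index=nodes,
    )
    return eio.ExpressionMatrix(vals), eio.SampleMetadata(pd.DataFrame(meta_rows))


class TestNodeScores:
    def _score(self, weights=None):
        # arcs only: degrees (2, 1, 1) so connectivity is non-degenerate
        net = grn.MixedNetwork()
        for n in ("tf1", "g2", "g3"):
            net.add_node(n, is_tf=(n == "tf1"))
        net.add_regulation("tf1", "g2", "tf_regulation")
        net.add_regulation("tf1", "g3", "tf_regulation")
        # tf1: max degree (2 arcs), max fold change, tau 0.9, TF
        X, meta = expression_for(
            ["tf1", "g2", "g3"],
            {"tf1": [8, 8, 1, 1], "g2": [2, 2, 2, 2], "g3": [3, 3, 2, 2]},
        )
        tsi = pd.DataFrame({"tau": [0.9, 0.2, 0.4]}, index=["tf1", "g2", "g3"])
        return sc.node_scores(net, X, meta, "lung", tsi, weights)

    def test_composite_is_weighted_sum_of_components(self):
        tab = self._score()
        expected = 0.25 * (
            tab["connectivity"] + tab["diffexpr"] + tab["tau"] + tab["is_tf"]
        )
        np.testing.assert_allclose(tab["S_node"], expected, atol=1e-12)

    def test_max_in_every_component_scores_one(self):
        tab = self._score()
        # tf1 is maximal in all four components
        assert tab.loc["tf1", "S_node"] == pytest.approx(
            0.25 * (1 + 1 + 0.9 + 1)
        )
        mod = self._score()
        assert mod["S_node"].idxmax() == "tf1"

    def test_isolated_flat_non_tf_scores_zero(self):
        net = small_net()
        net.add_node("lone")
        X, meta = expression_for(
            ["tf1", "g2", "g3", "lone"],
            {"tf1": [8, 8, 1, 1], "g2": [2, 2, 2, 2], "g3": [3, 3, 2, 2], "lone": [2, 2, 2, 2]},
        )
        tsi = pd.DataFrame({"tau": [0.9, 0.2, 0.4, 0.0]}, index=X.gene_ids)
        tab = sc.node_scores(net, X, meta, "lung", tsi)
        assert tab.loc["lone", "S_node"] == pytest.approx(0.0)

    def test_monotone_in_tau(self):
        base = self._score()
        net = grn.MixedNetwork()
        for n in ("tf1", "g2", "g3"):
            net.add_node(n, is_tf=(n == "tf1"))
        net.add_regulation("tf1", "g2", "tf_regulation")
        net.add_regulation("tf1", "g3", "tf_regulation")
        X, meta = expression_for(
            ["tf1", "g2", "g3"],
            {"tf1": [8, 8, 1, 1], "g2": [2, 2, 2, 2], "g3": [3, 3, 2, 2]},
        )
        tsi = pd.DataFrame({"tau": [0.9, 0.8, 0.4]}, index=["tf1", "g2", "g3"])
        bumped = sc.node_scores(net, X, meta, "lung", tsi)
        assert bumped.loc["g2", "S_node"] > base.loc["g2", "S_node"]
        assert bumped.loc["tf1", "S_node"] == pytest.approx(base.loc["tf1", "S_node"])

    def test_tf_only_weights_give_tf_first_ranking(self):
        w = sc.ScoreWeights(w_connectivity=0, w_diffexpr=0, w_tsi=0, w_tf=1)
        tab = self._score(w)
        assert tab.loc["tf1", "S_node"] == 1.0
        assert tab.loc[["g2", "g3"], "S_node"].max() == 0.0

    def test_degenerate_component_zeroed_with_warning(self):
        net = grn.MixedNetwork()
        for n in ("a", "b"):
            net.add_node(n)
        net.add_coexpression("a", "b", 0.5)
        X, meta = expression_for(["a", "b"], {"a": [1, 1, 1, 1], "b": [1, 1, 1, 1]})
        tsi = pd.DataFrame({"tau": [0.1, 0.1]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="degenerate"):
            tab = sc.node_scores(net, X, meta, "lung", tsi)
        assert (tab["connectivity"] == 0).all()
        assert (tab["diffexpr"] == 0).all()


class TestEdgeScores:
    def test_coexpression_weight_is_identity(self):
        net = small_net()
        A = pd.DataFrame(np.eye(3), index=["tf1", "g2", "g3"], columns=["tf1", "g2", "g3"])
        A.loc["g2", "g3"] = A.loc["g3", "g2"] = 0.73
        A.loc["tf1", "g2"] = A.loc["g2", "tf1"] = 1.0
        scores = sc.edge_scores(net, A)
        assert scores[("coexpression", ("g2", "g3"))] == pytest.approx(0.73)
        assert scores[("regulation", ("tf1", "g2"))] == pytest.approx(1.0)

    def test_mirna_arc_gets_documented_constant(self):
        net = grn.MixedNetwork()
        net.add_node("mir-1", is_mirna=True)
        net.add_node("g1")
        net.add_regulation("mir-1", "g1", "mirna_regulation")
        A = pd.DataFrame([[1.0]], index=["g1"], columns=["g1"])
        scores = sc.edge_scores(net, A)
        assert scores[("regulation", ("mir-1", "g1"))] == 0.5

    def test_independent_genes_score_near_zero_at_high_power(self):
        from triadnet import coexpression_network as cx

        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            rng.random((2, 30)), index=["u", "v"], columns=[f"s{i}" for i in range(30)]
        )
        A = cx.adjacency(eio.ExpressionMatrix(vals), 20)
        assert A.loc["u", "v"] < 1e-6


class TestMotifScores:
    def test_hand_mixture(self):
        net = small_net()
        node_tab = pd.DataFrame({"S_node": [1.0, 0.5, 0.5]}, index=["tf1", "g2", "g3"])
        edge_map = {
            ("regulation", ("tf1", "g2")): 0.8,
            ("regulation", ("tf1", "g3")): 0.6,
            ("coexpression", ("g2", "g3")): 0.7,
        }
        tab = sc.motif_scores([(10, ("tf1", "g2", "g3"))], node_tab, edge_map, net, alpha=0.5)
        expected = 0.5 * (2 / 3) + 0.5 * ((0.8 + 0.6 + 0.7) / 3)
        assert tab.iloc[0]["S_motif"] == pytest.approx(expected)

    def test_unit_and_zero_limits(self):
        net = small_net()
        ones = pd.DataFrame({"S_node": [1.0, 1.0, 1.0]}, index=["tf1", "g2", "g3"])
        edge_map = {k: 1.0 for k in sc.edge_scores(net, pd.DataFrame(np.ones((3, 3)), index=["tf1", "g2", "g3"], columns=["tf1", "g2", "g3"]))}
        tab = sc.motif_scores([(10, ("tf1", "g2", "g3"))], ones, edge_map, net)
        assert tab.iloc[0]["S_motif"] == pytest.approx(1.0)
        zeros = pd.DataFrame({"S_node": [0.0, 0.0, 0.0]}, index=["tf1", "g2", "g3"])
        tab = sc.motif_scores([(10, ("tf1", "g2", "g3"))], zeros, {}, net)
        assert tab.iloc[0]["S_motif"] == pytest.approx(0.0)


class TestRanking:
    def _table(self, n):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {"S_node": rng.random(n)}, index=[f"g{i:03d}" for i in range(n)]
        )

    def test_fraction_one_returns_everything(self):
        net = grn.MixedNetwork()
        tab = sc.rank_and_select(self._table(10), net, fraction=1.0)
        assert len(tab) == 10

    def test_ceil_convention_on_160_nodes(self):
        net = grn.MixedNetwork()
        tab = sc.rank_and_select(self._table(160), net, fraction=0.25)
        assert len(tab) == 40

    def test_super_node_ranks_first_and_ties_by_id(self):
        net = grn.MixedNetwork()
        df = pd.DataFrame({"S_node": [0.5, 0.9, 0.5]}, index=["gb", "ga", "gc"])
        tab = sc.rank_and_select(df, net, fraction=1.0)
        assert list(tab.index) == ["ga", "gb", "gc"]
        assert list(tab["rank"]) == [1, 2, 3]


class TestTopComplex:
    def _motif_table(self):
        return pd.DataFrame(
            [
                {"class_id": 10, "node_A": "a", "node_B": "b", "node_C": "c", "S_motif": 0.9},
                {"class_id": 10, "node_A": "x", "node_B": "y", "node_C": "z", "S_motif": 0.4},
                {"class_id": 7, "node_A": "a", "node_B": "b", "node_C": "t1", "S_motif": 0.5},
                {"class_id": 9, "node_A": "a", "node_B": "c", "node_C": "t2", "S_motif": 0.5},
                {"class_id": 7, "node_A": "a", "node_B": "b", "node_C": "t2", "S_motif": 0.5},
                {"class_id": 7, "node_A": "x", "node_B": "y", "node_C": "t9", "S_motif": 0.5},
            ]
        )

    def test_top_complex_and_co_regulated_targets(self):
        rep = sc.extract_top_complex(self._motif_table())
        assert rep.members == ("a", "b", "c")
        assert rep.n_motifs == 3
        got = dict(zip(rep.co_regulated["target"], rep.co_regulated["n_motifs"]))
        assert got == {"t1": 1, "t2": 2}

    def test_equal_scores_break_ties_deterministically(self):
        tab = pd.DataFrame(
            [
                {"class_id": 10, "node_A": "m", "node_B": "n", "node_C": "o", "S_motif": 0.7},
                {"class_id": 10, "node_A": "a", "node_B": "b", "node_C": "c", "S_motif": 0.7},
            ]
        )
        rep = sc.extract_top_complex(tab)
        assert rep.members == ("a", "b", "c")

    def test_no_class_ten_warns_and_returns_none(self):
        tab = pd.DataFrame(
            [{"class_id": 7, "node_A": "a", "node_B": "b", "node_C": "c", "S_motif": 1.0}]
        )
        with pytest.warns(UserWarning, match="class 10"):
            assert sc.extract_top_complex(tab) is None
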