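"""Mass-action strengths, flows, activation index, clustering, GO projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exsignet import (StateError, ValidationError, activation_index,
                      assign_expression, build_pair_matrix, cluster_pairs,
                      edge_strength, flow_summary, go_projection,
                      max_signal_flow, normalize_pair_matrix, weight_network)
from exsignet.quantify import PairStrengthMatrix
from conftest import make_gexpr, make_net, make_weighted, min_cut_bruteforce


def single_path_net(expr=(1.0, 2.0, 2.0, 1.0)):
    l, r, f, t = expr
    return make_net(
        [(("L1", "L"), ("R1", "R"), "LR"),
         (("R1", "R"), ("F1", "TF"), "RTF"),
         (("F1", "TF"), ("T1", "T"), "TFT")],
        node_expr={("L1", "L"): l, ("R1", "R"): r,
                   ("F1", "TF"): f, ("T1", "T"): t})


class TestEdgeStrength:
    def test_half_saturation_at_product_equal_kh(self):
        assert edge_strength(1.0, 2.0, kh=2.0) == 0.5

    def test_zero_expression_gives_zero(self):
        assert edge_strength(0.0, 5.0) == 0.0

    def test_direct_formula_value(self):
        assert edge_strength(2.0, 3.0, kh=2.0) == pytest.approx(0.75)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            edge_strength(-1.0, 1.0)
        with pytest.raises(ValidationError):
            edge_strength(1.0, 1.0, kh=0.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(0, 100), st.floats(0.01, 100), st.floats(0.1, 10))
    def test_bounded_and_monotone(self, s, delta, kh):
        w = edge_strength(s, s, kh)
        assert 0 <= w < 1
        assert edge_strength(s + delta, s, kh) >= w


class TestAssignExpression:
    def test_max_over_groups(self):
        gexpr = make_gexpr({"R1": {"A": 0.5, "B": 2.0},
                            "F1": {"A": 3.0, "B": 1.0},
                            "T1": {"A": 1.0, "B": 1.0}})
        net = single_path_net()
        net.node_expr = {}
        out = assign_expression(net, gexpr)
        assert out.node_expr[("R1", "R")] == 2.0
        assert out.node_expr[("F1", "TF")] == 3.0

    def test_external_signal_defaults_to_one(self):
        gexpr = make_gexpr({"R1": {"A": 1.0}, "F1": {"A": 1.0},
                            "T1": {"A": 1.0}})
        out = assign_expression(single_path_net(), gexpr)
        assert out.node_expr[("L1", "L")] == 1.0

    def test_named_group_overrides_max(self):
        gexpr = make_gexpr({"R1": {"A": 5.0, "B": 2.0},
                            "F1": {"A": 5.0, "B": 1.0},
                            "T1": {"A": 5.0, "B": 1.0}})
        out = assign_expression(single_path_net(), gexpr, group="B")
        assert out.node_expr[("R1", "R")] == 2.0

    def test_external_override_dataset(self):
        gexpr = make_gexpr({"R1": {"A": 1.0}, "F1": {"A": 1.0},
                            "T1": {"A": 1.0}})
        aux = make_gexpr({"L1": {"ext": 4.0}})
        out = assign_expression(single_path_net(), gexpr,
                                external_override=(aux, "ext"))
        assert out.node_expr[("L1", "L")] == 4.0

    def test_unknown_group_rejected(self):
        gexpr = make_gexpr({"R1": {"A": 1.0}})
        with pytest.raises(ValidationError):
            assign_expression(single_path_net(), gexpr, group="Z")


class TestWeightNetwork:
    def test_path_weights(self):
        w = weight_network(single_path_net(), kh=2.0)
        assert w.edge_strength[(("L1", "L"), ("R1", "R"))] == 0.5
        assert w.edge_strength[(("R1", "R"), ("F1", "TF"))] == pytest.approx(2 / 3)
        assert w.edge_strength[(("F1", "TF"), ("T1", "T"))] == 0.5

    def test_doubling_kh_weakly_decreases_weights(self):
        w1 = weight_network(single_path_net(), kh=2.0)
        w2 = weight_network(single_path_net(), kh=4.0)
        for e in w1.edge_strength:
            assert w2.edge_strength[e] <= w1.edge_strength[e]

    def test_rank_invariance_under_kh(self):
        # strictly ordered expression products give Kh-independent ranks
        rng = np.random.default_rng(3)
        exprs = rng.uniform(0.2, 5.0, size=4)
        net = single_path_net(tuple(exprs))
        ranks = None
        for kh in range(1, 11):
            w = weight_network(net, kh=float(kh))
            order = tuple(sorted(w.edge_strength,
                                 key=lambda e: w.edge_strength[e]))
            assert ranks is None or order == ranks
            ranks = order

    def test_unpopulated_expression_is_state_error(self):
        net = single_path_net()
        net.node_expr = {}
        with pytest.raises(StateError):
            weight_network(net)


class TestMaxFlow:
    def test_single_path_bottleneck(self):
        w = weight_network(single_path_net(), kh=2.0)
        assert max_signal_flow(w, "L1", "T1") == pytest.approx(0.5)

    def test_disconnected_pair_is_zero(self):
        w = make_weighted([
            (("L1", "L"), ("R1", "R"), "LR", 0.5),
            (("R1", "R"), ("F1", "TF"), "RTF", 0.5),
            (("F1", "TF"), ("T1", "T"), "TFT", 0.5),
            (("L2", "L"), ("R2", "R"), "LR", 0.5),
            (("R2", "R"), ("F2", "TF"), "RTF", 0.5),
            (("F2", "TF"), ("T2", "T"), "TFT", 0.5),
        ])
        assert max_signal_flow(w, "L1", "T2") == 0.0

    def test_parallel_paths_add(self):
        w = make_weighted([
            (("L1", "L"), ("R1", "R"), "LR", 0.3),
            (("R1", "R"), ("F1", "TF"), "RTF", 0.9),
            (("F1", "TF"), ("T1", "T"), "TFT", 0.8),
            (("L1", "L"), ("R2", "R"), "LR", 0.4),
            (("R2", "R"), ("F2", "TF"), "RTF", 0.9),
            (("F2", "TF"), ("T1", "T"), "TFT", 0.9),
        ])
        assert max_signal_flow(w, "L1", "T1") == pytest.approx(0.7)

    def test_absent_nodes_rejected(self):
        w = weight_network(single_path_net())
        with pytest.raises(ValidationError):
            max_signal_flow(w, "nope", "T1")
        with pytest.raises(ValidationError):
            max_signal_flow(w, "L1", "nope")

    def test_matches_bruteforce_min_cut_on_random_layered_graphs(self):
        rng = np.random.default_rng(11)
        from exsignet.quantify import _capacity_graph
        for _ in range(40):
            w = _random_layered_weighted(rng)
            g = _capacity_graph(w)
            lig = sorted(w.net.external_signals)[0]
            for t in w.net.targets:
                expected = min_cut_bruteforce(g, (lig, "L"), (t, "T"))
                assert max_signal_flow(w, lig, t) == pytest.approx(
                    expected, abs=1e-9)


def _random_layered_weighted(rng, max_per_layer=2):
    """Random 4-layer weighted net with <= 8 nodes and random capacities."""
    sizes = rng.integers(1, max_per_layer + 1, size=4)
    layers = [[(f"{tag}{i}", role) for i in range(sizes[j])]
              for j, (tag, role) in enumerate(
                  [("L", "L"), ("R", "R"), ("F", "TF"), ("T", "T")])]
    edges = []
    for (a_nodes, b_nodes), layer in zip(zip(layers, layers[1:]),
                                         ("LR", "RTF", "TFT")):
        for a in a_nodes:
            for b in b_nodes:
                if rng.random() < 0.7:
                    edges.append((a, b, layer, float(rng.uniform(0.05, 0.95))))
    if not edges:
        edges = [(layers[0][0], layers[1][0], "LR", 0.5)]
    w = make_weighted(edges)
    # register every layer node even if isolated
    for lay in layers:
        w.net.graph.add_nodes_from(lay)
        for n in lay:
            w.net.node_expr.setdefault(n, 1.0)
    w.net.external_signals = {g for g, r in layers[0]}
    return w


class TestFlowSummary:
    def test_single_path_critical_nodes(self):
        w = weight_network(single_path_net())
        res = flow_summary(w)
        assert res.critical_signal == "L1" and res.critical_target == "T1"

    def test_dominating_ligand_is_critical(self):
        w = make_weighted([
            (("LA", "L"), ("R1", "R"), "LR", 0.9),
            (("LB", "L"), ("R1", "R"), "LR", 0.2),
            (("R1", "R"), ("F1", "TF"), "RTF", 0.9),
            (("F1", "TF"), ("T1", "T"), "TFT", 0.9),
        ])
        assert flow_summary(w).critical_signal == "LA"

    def test_conservation_of_total_flow(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            w = _random_layered_weighted(rng, max_per_layer=3)
            res = flow_summary(w)
            assert sum(res.total_outflow.values()) == pytest.approx(
                sum(res.total_inflow.values()))
            assert all(f >= 0 for f in res.pair_flow.values())
            for l, out in res.total_outflow.items():
                assert out == pytest.approx(
                    sum(f for (l2, _), f in res.pair_flow.items() if l2 == l))


class TestActivationIndex:
    def test_zero_layer_strength_gives_zero(self):
        w = make_weighted([
            (("L1", "L"), ("R1", "R"), "LR", 0.0),
            (("R1", "R"), ("F1", "TF"), "RTF", 0.5),
            (("F1", "TF"), ("T1", "T"), "TFT", 0.5),
        ])
        assert activation_index(w) == 0.0

    def test_worked_example_closed_form(self):
        w = weight_network(single_path_net(), kh=2.0)
        expected = (12 / 14) * (0.5 / 2.5) * ((2 / 3) / (2 + 2 / 3)) * (0.5 / 2.5)
        assert activation_index(w) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_each_edge_strength(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            w = _random_layered_weighted(rng)
            base = activation_index(w)
            assert 0 <= base < 1
            for e in w.edge_strength:
                bumped = {**w.edge_strength,
                          e: min(0.999, w.edge_strength[e] + 0.05)}
                w2 = type(w)(net=w.net, edge_strength=bumped)
                if all(w.layer_total(l) > 0 for l in ("LR", "RTF", "TFT")):
                    assert activation_index(w2) > base

    def test_invalid_constants(self):
        w = weight_network(single_path_net())
        with pytest.raises(ValidationError):
            activation_index(w, k=(0.0, 2, 2, 2))


class TestPairMatrix:
    def test_single_path_matrix(self):
        w = weight_network(single_path_net())
        pm = build_pair_matrix(w)
        assert pm.W.shape == (1, 3)
        assert sorted(pm.W[0]) == pytest.approx([0.5, 0.5, 2 / 3])

    def test_unconnected_pair_has_zero_row(self):
        w = make_weighted([
            (("L1", "L"), ("R1", "R"), "LR", 0.5),
            (("R1", "R"), ("F1", "TF"), "RTF", 0.5),
            (("F1", "TF"), ("T1", "T"), "TFT", 0.5),
            (("L2", "L"), ("R2", "R"), "LR", 0.5),
            (("R2", "R"), ("F2", "TF"), "RTF", 0.5),
            (("F2", "TF"), ("T2", "T"), "TFT", 0.5),
        ])
        pm = build_pair_matrix(w)
        assert pm.W.shape == (4, 6)
        row = pm.rows.index(("L1", "T2"))
        assert (pm.W[row] == 0).all()

    def test_shared_edge_nonzero_in_both_rows(self):
        w = make_weighted([
            (("L1", "L"), ("R1", "R"), "LR", 0.4),
            (("L2", "L"), ("R1", "R"), "LR", 0.5),
            (("R1", "R"), ("F1", "TF"), "RTF", 0.6),
            (("F1", "TF"), ("T1", "T"), "TFT", 0.7),
        ])
        pm = build_pair_matrix(w)
        col = pm.cols.index((("F1", "TF"), ("T1", "T")))
        assert pm.W[pm.rows.index(("L1", "T1")), col] == 0.7
        assert pm.W[pm.rows.index(("L2", "T1")), col] == 0.7

    def test_shape_is_pairs_by_edges(self):
        rng = np.random.default_rng(13)
        w = _random_layered_weighted(rng, max_per_layer=3)
        pm = build_pair_matrix(w)
        n_l = len(w.net.external_signals)
        n_t = len(w.net.targets)
        assert pm.W.shape == (n_l * n_t, w.net.graph.number_of_edges())


class TestClustering:
    def _pm(self, W):
        W = np.asarray(W, float)
        rows = [(f"L{i}", "T0") for i in range(W.shape[0])]
        cols = [((f"A{j}", "L"), (f"B{j}", "R")) for j in range(W.shape[1])]
        return PairStrengthMatrix(rows=rows, cols=cols, W=np.asarray(W, float))

    def test_two_groups_of_identical_rows(self):
        pm = self._pm([[1, 0, 0], [1, 0, 0], [0, 0, 1], [0, 0, 1]])
        labels = cluster_pairs(pm, k=2, seed=0)
        assert labels[("L0", "T0")] == labels[("L1", "T0")]
        assert labels[("L2", "T0")] == labels[("L3", "T0")]
        assert labels[("L0", "T0")] != labels[("L2", "T0")]

    def test_k_equal_one(self):
        pm = self._pm([[1, 0], [0, 1]])
        assert set(cluster_pairs(pm, k=1, seed=0).values()) == {0}

    def test_duplicated_rows_co_cluster(self):
        rng = np.random.default_rng(17)
        base = rng.uniform(size=(3, 5))
        W = np.vstack([base, base])
        pm = self._pm(W)
        for k in (2, 3):
            labels = cluster_pairs(pm, k=k, seed=1)
            for i in range(3):
                assert labels[(f"L{i}", "T0")] == labels[(f"L{i + 3}", "T0")]

    def test_k_out_of_range(self):
        pm = self._pm([[1, 0], [1, 0]])
        with pytest.raises(ValidationError):
            cluster_pairs(pm, k=2, seed=0)  # only one distinct row

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(19)
        pm = self._pm(rng.uniform(size=(6, 4)))
        assert cluster_pairs(pm, 3, seed=7) == cluster_pairs(pm, 3, seed=7)

    def test_row_unit_normalization(self):
        pm = self._pm([[3, 4], [0, 0]])
        norm = normalize_pair_matrix(pm)
        assert np.allclose(norm.W[0], [0.6, 0.8])
        assert (norm.W[1] == 0).all()


class TestGOProjection:
    def _wnet(self):
        net = single_path_net(expr=(1.0, 2.0, 2.0, 1.0))
        return weight_network(net)

    def test_term_covering_everything(self):
        proj = go_projection(self._wnet(), {"all": {"L1", "R1", "F1", "T1"}})
        assert proj["all"].gene_proportion == 1.0
        assert proj["all"].expression_proportion == 1.0

    def test_disjoint_term(self):
        proj = go_projection(self._wnet(), {"none": {"X", "Y"}})
        assert proj["none"].gene_proportion == 0.0
        assert proj["none"].expression_proportion == 0.0
        assert proj["none"].genes == set()

    def test_hand_computed_proportions(self):
        # node expressions {1, 2, 2, 1}; term hits the two 2's
        proj = go_projection(self._wnet(), {"mid": {"R1", "F1"}})
        assert proj["mid"].gene_proportion == 0.5
        assert proj["mid"].expression_proportion == pytest.approx(4 / 6)

    def test_empty_network_is_state_error(self):
        net = make_net([])
        w = type(self._wnet())(net=net, edge_strength={})
        with pytest.raises(StateError):
            go_projection(w, {"t": {"A"}})
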