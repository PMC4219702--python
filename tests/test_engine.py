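"""Engine unit tests: state codec, rule evaluation, successor map,
trajectories, attractor enumeration, transition graphs, model I/O."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caulocycle.engine import (
    LogicalNetwork,
    NetworkError,
    NodeDecl,
    StateSpaceCapExceeded,
    UpdateRule,
    decode_state,
    encode_state,
    enumerate_attractors,
    evaluate_rule,
    format_case,
    parse_case,
    parse_condition,
    successor,
    trajectory,
    transition_graph,
    truth_table,
)
from caulocycle.modelio import load_model, model_from_dict, model_to_dict, save_model


def _net(nodes, rules_spec, clamps=None):
    decls = [NodeDecl(n, c) for n, c in nodes]
    rules = {
        n: UpdateRule(target=n, cases=tuple(parse_case(c) for c in cases), default=d)
        for n, (cases, d) in rules_spec.items()
    }
    return LogicalNetwork(decls, rules, clamps=clamps)


@pytest.fixture
def two_node():
    # x boolean, y ternary: y' copies x+... simple rules for codec tests
    return _net(
        [("x", 1), ("y", 2)],
        {"x": (["y>=1 -> 1"], 0), "y": (["x>=1 -> 2"], 0)},
    )


class TestStateCodec:
    def test_all_zero_maps_to_index_zero(self, two_node, g2a):
        assert encode_state(two_node, (0, 0)) == 0
        assert encode_state(g2a, (0,) * 5) == 0

    def test_mixed_radix_bijection(self, two_node):
        assert two_node.state_space_size == 6
        seen = {encode_state(two_node, s) for s in itertools.product(range(2), range(3))}
        assert seen == set(range(6))

    def test_round_trip_exhaustive_g2a(self, g2a):
        assert g2a.state_space_size == 32
        for i in range(32):
            assert encode_state(g2a, decode_state(g2a, i)) == i

    def test_out_of_range_rejected(self, two_node):
        with pytest.raises(NetworkError):
            decode_state(two_node, 6)
        with pytest.raises(NetworkError):
            encode_state(two_node, (0, 3))


class TestRuleEvaluation:
    def test_dnaa_requires_ctra_and_ccrm_without_repressors(self, g2a):
        rule = g2a.rules["DnaA"]
        s = g2a.state(CtrA=1, CcrM=1)
        assert evaluate_rule(g2a, rule, s) == 1

    def test_dnaa_self_repression(self, g2a):
        rule = g2a.rules["DnaA"]
        s = g2a.state(CtrA=1, CcrM=1, DnaA=1)
        assert evaluate_rule(g2a, rule, s) == 0

    def test_dnaa_blocked_by_gcra(self, g2a):
        rule = g2a.rules["DnaA"]
        s = g2a.state(CtrA=1, CcrM=1, GcrA=1)
        assert evaluate_rule(g2a, rule, s) == 0

    def test_clamp_ignored_by_rule_evaluation(self, g2a):
        clamped = g2a.with_clamps({"SciP": 0})
        s = clamped.state(CtrA=1)
        assert evaluate_rule(clamped, clamped.rules["SciP"], s) == 1
        assert successor(clamped, s)[clamped.index["SciP"]] == 0

    def test_first_matching_case_wins(self, g2b):
        # phosphatase case precedes the kinase case in DivK's rule
        s = g2b.state(PleC=2, DivJ=2)
        assert evaluate_rule(g2b, g2b.rules["DivK"], s) == 1


class TestSuccessor:
    def test_g2a_gcra_only_hands_off_to_ctra(self, g2a):
        b = g2a.state(GcrA=1)
        assert successor(g2a, b) == g2a.state(CtrA=1)

    def test_g2a_division_state_hands_off_to_dnaa_scip(self, g2a):
        d = g2a.state(CtrA=1, CcrM=1, SciP=1)
        assert successor(g2a, d) == g2a.state(DnaA=1, SciP=1)

    def test_full_clamping_forces_clamp_vector(self, two_node):
        net = two_node.with_clamps({"x": 1, "y": 2})
        for s in itertools.product(range(2), range(3)):
            assert successor(net, s) == (1, 2)

    def test_successor_is_pure(self, g2b):
        s = g2b.state(DivJ=2)
        assert successor(g2b, s) == successor(g2b, s)


class TestTrajectory:
    def test_enters_g2a_cycle_quickly(self, g2a):
        path = trajectory(g2a, (0,) * 5)
        assert path[-1] in path[:-1]
        assert len(path) <= 7  # transient <= 5 steps into the 4-cycle

    def test_fixed_point_trajectory_has_length_two(self, g2b):
        i_state = g2b.state(CtrA=2, DivK=1, DivJ=1, PleC=2, DivL=1, CckA=2, ChpT=2, CpdR=2)
        assert trajectory(g2b, i_state) == [i_state, i_state]

    def test_max_steps_too_small_raises(self, g2a):
        with pytest.raises(RuntimeError):
            # a 4-cycle cannot be closed in one step from outside
            trajectory(g2a, g2a.state(DnaA=1), max_steps=1)


class TestEnumerateAttractors:
    def test_constant_network_single_fixed_point(self):
        net = _net([("a", 1), ("b", 2)], {"a": ([], 1), "b": ([], 2)})
        rep = enumerate_attractors(net)
        assert len(rep.attractors) == 1
        assert rep.attractors[0].states == ((1, 2),)
        assert rep.basin_sizes == (6,)

    def test_negation_ring_cycle_structure(self, fixtures):
        rep = enumerate_attractors(fixtures["negation_ring3"])
        lengths = sorted(len(a) for a in rep.attractors)
        assert lengths == [2, 6]
        two = next(a for a in rep.attractors if len(a) == 2)
        assert set(two.states) == {(0, 0, 0), (1, 1, 1)}
        assert sorted(rep.basin_sizes) == [2, 6]

    def test_basins_partition_state_space(self, g2b):
        rep = enumerate_attractors(g2b)
        assert sum(rep.basin_sizes) == rep.state_space_size == 8748

    def test_cycle_closes_in_exactly_its_length(self, g2a):
        rep = enumerate_attractors(g2a)
        (att,) = rep.attractors
        s = att.states[0]
        for k in range(1, len(att)):
            s = successor(g2a, s)
            assert s != att.states[0]
        assert successor(g2a, s) == att.states[0]

    def test_clamp_dominance_in_attractors(self, g2b):
        net = g2b.with_clamps({"DivK": 0})
        rep = enumerate_attractors(net)
        i = net.index["DivK"]
        assert all(s[i] == 0 for a in rep.attractors for s in a.states)

    def test_state_space_cap_guard(self, g2b):
        with pytest.raises(StateSpaceCapExceeded):
            enumerate_attractors(g2b, cap=100)


class TestTransitionGraph:
    def test_out_degree_one_and_edge_count(self, g2a):
        tg = transition_graph(g2a)
        assert len(tg.edges) == 32
        g = tg.to_networkx()
        assert all(d == 1 for _, d in g.out_degree())

    def test_g2b_graph_has_exactly_two_self_loops(self, g2b):
        tg = transition_graph(g2b)
        self_loops = [i for i, j in enumerate(tg.edges) if i == j]
        assert len(self_loops) == 2
        assert len(tg.states) == 8748

    def test_consistent_with_successor(self, fixtures):
        net = fixtures["toggle2"]
        tg = transition_graph(net)
        for i, j in enumerate(tg.edges):
            assert successor(net, tg.states[i]) == tg.states[j]

    def test_dot_and_graphml_export(self, tmp_path, fixtures):
        import networkx as nx

        from caulocycle.modelio import export_transition_graph

        tg = transition_graph(fixtures["negation_ring3"])
        dot = tmp_path / "tg.dot"
        gml = tmp_path / "tg.graphml"
        export_transition_graph(tg, dot)
        export_transition_graph(tg, gml)
        assert dot.read_text().count("->") == 8
        back = nx.read_graphml(gml)
        assert back.number_of_nodes() == 8 and back.number_of_edges() == 8


class TestConditionSyntax:
    @pytest.mark.parametrize(
        "text,n_literals",
        [("CtrA==2 & CcrM>=1 & !GcrA & !DnaA", 4), ("x", 1), ("!x", 1), ("*", 0), ("", 0)],
    )
    def test_parse_condition_shapes(self, text, n_literals):
        assert len(parse_condition(text)) == n_literals

    def test_bare_name_means_at_least_one(self):
        (lit,) = parse_condition("CtrA")
        assert (lit.relation, lit.level) == (">=", 1)
        (neg,) = parse_condition("!CtrA")
        assert (neg.relation, neg.level) == ("==", 0)

    def test_case_round_trip(self):
        case = parse_case("CtrA==2 & CcrM>=1 & !GcrA -> 1")
        assert parse_case(format_case(case)) == case

    def test_garbage_rejected(self):
        with pytest.raises(NetworkError):
            parse_case("CtrA ==")
        with pytest.raises(NetworkError):
            parse_condition("!CtrA==2")


class TestTruthTable:
    def test_expansion_matches_direct_evaluation(self, g2a):
        table = truth_table(g2a, "DnaA")
        inputs = g2a.rules["DnaA"].inputs()
        assert set(inputs) == {"CtrA", "CcrM", "GcrA", "DnaA"}
        for combo, out in table.items():
            s = g2a.state(dict(zip(inputs, combo)))
            assert evaluate_rule(g2a, g2a.rules["DnaA"], s) == out

    def test_multivalued_inputs_expanded_to_their_caps(self, g2b):
        table = truth_table(g2b, "CtrA")
        # inputs ClpXP_RcdA (0..1) and ChpT (0..2): 6 rows
        assert len(table) == 6


class TestModelIO:
    def test_yaml_round_trip(self, tmp_path, g2b):
        path = tmp_path / "model.yaml"
        save_model(g2b, path)
        assert load_model(path) == g2b

    def test_json_round_trip(self, tmp_path, g2a):
        path = tmp_path / "model.json"
        save_model(g2a, path)
        assert load_model(path) == g2a

    def test_clamps_survive_round_trip(self, tmp_path, g2b):
        net = g2b.with_clamps({"DivK": 0})
        path = tmp_path / "model.yaml"
        save_model(net, path)
        assert load_model(path).clamps == {"DivK": 0}

    def test_dict_round_trip(self, g2):
        assert model_from_dict(model_to_dict(g2)) == g2


class TestValidation:
    def test_rule_for_undeclared_node_rejected(self):
        with pytest.raises(NetworkError):
            _net([("a", 1)], {"a": (["b>=1 -> 1"], 0)})

    def test_output_beyond_cap_rejected(self):
        with pytest.raises(NetworkError):
            _net([("a", 1)], {"a": ([], 2)})

    def test_missing_rule_rejected(self):
        with pytest.raises(NetworkError):
            LogicalNetwork([NodeDecl("a"), NodeDecl("b")], {"a": UpdateRule("a", (), 0)})

    def test_conflicting_clamp_rejected(self, g2b):
        net = g2b.with_clamps({"DivK": 0})
        with pytest.raises(NetworkError):
            net.with_clamps({"DivK": 2})


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_codec_bijection_on_random_networks(seed):
    """decode(encode(s)) == s over networks with random caps."""
    import numpy as np

    rng = np.random.default_rng(seed)
    caps = [int(rng.integers(1, 4)) for _ in range(int(rng.integers(1, 6)))]
    net = _net([(f"v{i}", c) for i, c in enumerate(caps)], {f"v{i}": ([], 0) for i in range(len(caps))})
    for _ in range(10):
        s = tuple(int(rng.integers(0, c + 1)) for c in caps)
        assert decode_state(net, encode_state(net, s)) == s
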