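"""Caulobacter model tests: interaction catalogue, core reduction, and
the reference rule sets' dynamics."""

import pandas as pd
import pytest

from caulocycle.engine import enumerate_attractors, successor
from caulocycle.modelio import load_model
from caulocycle.models import (
    InteractionRecord,
    RegulatoryGraph,
    build_g2a,
    build_g2b,
    build_g2_combined,
    load_interactions,
    packaged_interaction_table,
    packaged_model_path,
    reduce_to_core,
)
from caulocycle.engine import NetworkError


def _graph(edge_triples):
    records = tuple(
        InteractionRecord(a, b, "positive", "transcription", "0") for a, b in edge_triples
    )
    nodes = []
    for a, b in edge_triples:
        for x in (a, b):
            if x not in nodes:
                nodes.append(x)
    return RegulatoryGraph(tuple(nodes), records)


class TestInteractionTable:
    def test_packaged_core_table_counts(self):
        g = load_interactions(packaged_interaction_table())
        assert g.n_nodes == 13
        assert g.n_edges == 27

    def test_core_table_is_already_reduced(self):
        g = load_interactions(packaged_interaction_table())
        core = reduce_to_core(g)
        assert set(core.nodes) == set(g.nodes)
        assert core.n_edges == g.n_edges

    def test_empty_table_gives_empty_graph(self):
        df = pd.DataFrame(columns=["regulator", "target", "sign", "mechanism", "evidence"])
        g = load_interactions(df)
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_unknown_vocabulary_rejected(self):
        df = pd.DataFrame(
            [{"regulator": "a", "target": "b", "sign": "up", "mechanism": "transcription", "evidence": ""}]
        )
        with pytest.raises(NetworkError):
            load_interactions(df)
        df2 = pd.DataFrame(
            [{"regulator": "a", "target": "b", "sign": "positive", "mechanism": "magic", "evidence": ""}]
        )
        with pytest.raises(NetworkError):
            load_interactions(df2)

    def test_missing_column_rejected(self):
        df = pd.DataFrame([{"regulator": "a", "target": "b"}])
        with pytest.raises(NetworkError):
            load_interactions(df)


class TestReduction:
    def test_chain_collapses_to_nothing(self):
        g = _graph([("a", "b"), ("b", "c")])
        assert reduce_to_core(g).n_nodes == 0

    def test_cycle_with_leaf_keeps_cycle(self):
        g = _graph([("a", "b"), ("b", "a"), ("a", "x")])
        core = reduce_to_core(g)
        assert set(core.nodes) == {"a", "b"}
        assert core.n_edges == 2

    def test_self_loop_counts_as_out_edge(self):
        # a's only out-edges are a self-loop and a link to the leaf x;
        # x goes, a stays (the self-loop keeps its out-degree positive)
        g = _graph([("a", "a"), ("a", "x")])
        core = reduce_to_core(g)
        assert set(core.nodes) == {"a"}
        assert core.n_edges == 1

    def test_idempotent(self):
        g = _graph([("a", "b"), ("b", "a"), ("a", "x"), ("x", "y"), ("c", "x")])
        once = reduce_to_core(g)
        twice = reduce_to_core(once)
        assert once == twice
        # no out-degree-0 node survives
        regulators = {e.regulator for e in once.edges}
        assert set(once.nodes) <= regulators


class TestG2aDynamics:
    def test_unique_four_state_cycle_with_full_basin(self, g2a):
        rep = enumerate_attractors(g2a)
        assert len(rep.attractors) == 1
        (att,) = rep.attractors
        assert att.kind == "limit_cycle" and len(att) == 4
        assert rep.basin_sizes == (32,)

    def test_cycle_visits_the_cell_cycle_stage_pattern(self, g2a):
        (att,) = enumerate_attractors(g2a).attractors
        # locate the replication-initiation state (DnaA and SciP on) and
        # check the progression: -> GcrA only -> CtrA only -> CtrA+CcrM+SciP
        states = list(att.states)
        a = g2a.state(DnaA=1, SciP=1)
        k = states.index(a)
        ordered = states[k:] + states[:k]
        assert ordered == [
            g2a.state(DnaA=1, SciP=1),
            g2a.state(GcrA=1),
            g2a.state(CtrA=1),
            g2a.state(CtrA=1, CcrM=1, SciP=1),
        ]

    def test_all_zero_state_is_not_fixed(self, g2a):
        nxt = successor(g2a, (0,) * 5)
        assert nxt[g2a.index["CtrA"]] == 1


class TestG2bDynamics:
    def test_exactly_two_fixed_points(self, g2b):
        rep = enumerate_attractors(g2b)
        assert len(rep.attractors) == 2
        assert not rep.limit_cycles
        assert rep.state_space_size == 8748

    def test_fixed_points_match_the_two_microdomains(self, g2b):
        rep = enumerate_attractors(g2b)
        states = {a.states[0] for a in rep.fixed_points}
        swarmer = g2b.state(
            CtrA=2, DivK=1, DivJ=1, PleC=2, DivL=1, CckA=2, ChpT=2, CpdR=2, ClpXP_RcdA=0
        )
        stalked = g2b.state(
            CtrA=0, DivK=2, DivJ=2, PleC=1, DivL=0, CckA=1, ChpT=1, CpdR=1, ClpXP_RcdA=1
        )
        assert states == {swarmer, stalked}

    def test_core_switch_module_is_bistable(self, g2b):
        # restricted to (DivK, DivJ, PleC) in {1,2}^3 with the rest held at
        # the swarmer fixed point, the kinase/phosphatase triangle has the
        # two expected fixed points and no other recurrent pattern
        import itertools

        fixed = []
        for divk, divj, plec in itertools.product((1, 2), repeat=3):
            s = g2b.state(
                CtrA=2, DivK=divk, DivJ=divj, PleC=plec, DivL=1, CckA=2, ChpT=2, CpdR=2
            )
            nxt = successor(g2b, s)
            idx = [g2b.index[n] for n in ("DivK", "DivJ", "PleC")]
            if tuple(nxt[i] for i in idx) == (divk, divj, plec):
                fixed.append((divk, divj, plec))
        assert sorted(fixed) == [(1, 1, 2), (2, 2, 1)]


class TestCombinedModel:
    def test_node_count_and_state_space(self, g2):
        assert g2.n_nodes == 13
        assert g2.state_space_size == 3**7 * 2**6 == 139_968

    def test_ctra_rule_reduces_to_transcriptional_gate_under_clamps(self, g2):
        # with proteolysis off and the relay charged, CtrA follows the
        # transcriptional gate at level 2
        clamped = g2.with_clamps({"ClpXP_RcdA": 0, "ChpT": 2})
        for gcra, ccrm, scip in [(1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)]:
            s = clamped.state(GcrA=gcra, CcrM=ccrm, SciP=scip, ChpT=2)
            gate = gcra or (not ccrm and not scip)
            assert successor(clamped, s)[g2.index["CtrA"]] == (2 if gate else 0)

    def test_projection_onto_transcriptional_subnetwork(self, g2, g2a):
        """Under a charged relay (ChpT=2, no proteolysis) the combined
        model's transcriptional coordinates move exactly like the Boolean
        subnetwork, with CtrA level 2 standing in for CtrA = 1."""
        import itertools

        clamped = g2.with_clamps({"ClpXP_RcdA": 0, "ChpT": 2})
        cols = [g2.index[n] for n in ("CtrA", "GcrA", "DnaA", "CcrM", "SciP")]
        for bits in itertools.product((0, 1), repeat=5):
            sa = bits
            sc = clamped.state(
                CtrA=2 * bits[0], GcrA=bits[1], DnaA=bits[2], CcrM=bits[3], SciP=bits[4], ChpT=2
            )
            na = successor(g2a, sa)
            nc = successor(clamped, sc)
            projected = tuple(nc[i] for i in cols)
            expected = (2 * na[0], na[1], na[2], na[3], na[4])
            assert projected == expected

    def test_combined_attractor_landscape(self, g2):
        # one stalked fixed point plus the swarmer-side oscillation
        rep = enumerate_attractors(g2)
        assert sum(rep.basin_sizes) == 139_968
        assert len(rep.fixed_points) == 1
        fp = rep.fixed_points[0].states[0]
        assert fp[g2.index["CtrA"]] == 0 and fp[g2.index["ClpXP_RcdA"]] == 1


class TestPackagedModelFiles:
    @pytest.mark.parametrize("which,builder", [
        ("g2a", build_g2a), ("g2b", build_g2b), ("g2", build_g2_combined),
    ])
    def test_packaged_file_identical_to_builder(self, which, builder):
        assert load_model(packaged_model_path(which)) == builder()
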