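"""Biological query recipes and their set identities."""

import json

import pytest

from grnmc.checker import Model, evaluate, steady_state_report
from grnmc.fixtures import TABLE2_PROFILES, profile_index
from grnmc.network import parse_equations
from grnmc.oracle import cycle_states_scc
from grnmc.random_nets import random_grn
from grnmc.recipes import (
    attractor_states,
    basin,
    mutant_screen,
    query_result,
    reach_avoiding,
    reach_through,
    small_attractor_basin_complement,
    terminal_attractors,
    two_cycle_states,
)
from grnmc.statespace import encode


class TestAttractors:
    def test_two_parallel_two_cycles_cover_the_whole_space(self):
        # A:=B; B:=A synchronous: (0,1) <-> (1,0) and two fixed points
        m = Model(parse_equations("A := B; B := A;"), "sync", "explicit")
        assert len(attractor_states(m)) == 4

    def test_fixed_point_only_network_attractors_equal_stable_set(self, root_grn):
        m = Model(root_grn, "async")
        stable, _ = steady_state_report(m)
        att = attractor_states(m)
        assert att == stable
        assert len(att) == 7

    def test_oscillator_two_cycle_states(self):
        m = Model(parse_equations("A := ~ A;"), "sync", "explicit")
        assert set(two_cycle_states(m).indices()) == {0, 1}
        # a fixed point is never in a two-cycle
        m2 = Model(parse_equations("A := A;"), "sync", "explicit")
        assert len(two_cycle_states(m2)) == 0

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("mode", ["sync", "async"])
    def test_attractor_formula_equals_scc_oracle(self, seed, mode):
        g = random_grn(5, 2, 0.1 if seed % 2 else 0.0, seed=seed)
        m = Model(g, mode)
        assert set(attractor_states(m).indices()) == set(cycle_states_scc(g, mode))

    def test_three_cycle_escapes_small_attractor_basins(self):
        # A:=C; B:=A; C:=B synchronous has fixed points and 3-cycles
        m = Model(parse_equations("A := C; B := A; C := B;"), "sync", "explicit")
        comp = small_attractor_basin_complement(m)
        assert len(comp) == 6  # the two 3-cycles
        # and a fixed-point-only network has an empty complement
        m2 = Model(parse_equations("A := A; B := B;"), "sync", "explicit")
        assert len(small_attractor_basin_complement(m2)) == 0


class TestReachability:
    def test_basin_contains_target_and_matches_backward_bfs(self, root_grn):
        m = Model(root_grn, "async")
        qc = m.rel.singleton(profile_index(root_grn, TABLE2_PROFILES["QC"]))
        b = basin(m, qc)
        assert qc.issubset(b)
        # independent reverse BFS on the explicit graph
        from grnmc.oracle import successor_lists

        succs = successor_lists(root_grn, "async")
        target = qc.indices()[0]
        seen = {target}
        frontier = [target]
        while frontier:
            nxt = [
                s
                for s in range(512)
                if s not in seen and succs[s] & seen
            ]
            seen.update(nxt)
            frontier = nxt
        assert set(b.indices()) == seen

    def test_basin_of_empty_set_is_empty(self, root_grn):
        m = Model(root_grn, "async")
        assert len(basin(m, m.rel.empty())) == 0

    def test_reach_avoiding_with_nothing_to_avoid_is_the_basin(self, root_grn):
        m = Model(root_grn, "async")
        target = m.rel.singleton(profile_index(root_grn, TABLE2_PROFILES["CEI"]))
        assert reach_avoiding(m, target, m.rel.empty()) == basin(m, target)

    def test_reach_through_on_a_chain(self):
        # (0,0) -> (1,0) -> (1,1) -> itself: reaching the sink requires the
        # middle state from the start
        m = Model(parse_equations("A := 1; B := A;"), "sync", "explicit")
        s0, s1, s2 = encode((0, 0)), encode((1, 0)), encode((1, 1))
        through = reach_through(m, m.rel.singleton(s2), m.rel.singleton(s1))
        # (0,1) also steps onto the middle state before the sink
        assert set(through.indices()) == {s0, s1, encode((0, 1))}

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_identity_on_random_networks(self, seed):
        g = random_grn(5, 2, 0.1, seed=seed)
        m = Model(g, "async")
        target = evaluate(m, "g0 and g1")
        via = evaluate(m, "not g2") - target
        union = reach_avoiding(m, target, via) | reach_through(m, target, via)
        assert union == basin(m, target)


class TestMutantScreen:
    def test_jkd_knockout_report(self, root_grn):
        m = Model(root_grn, "async")
        report = mutant_screen(m, "JKD", 0)
        stable = report["stable"]
        # CEI (JKD=1) can no longer be a fixed point
        cei = profile_index(root_grn, TABLE2_PROFILES["CEI"])
        assert cei not in stable.state_indices
        assert stable.count < 7

    def test_clamping_an_already_clamped_gene_is_a_no_op(self, root_grn):
        once = Model(root_grn.perturb("JKD", 0), "async")
        base_stable, base_unstable = steady_state_report(once)
        report = mutant_screen(once, "JKD", 0)
        assert report["stable"].state_indices == list(base_stable.indices())
        assert report["unstable"].count == len(base_unstable)

    def test_gain_of_function_restricts_stable_states_to_active_branch(
        self, root_grn
    ):
        m = Model(root_grn, "async")
        base = steady_state_report(m)[0]
        report = mutant_screen(m, "AUXINS", 1)
        kept = [s for s in base.indices() if s in m.rel.gene_true("AUXINS")]
        assert report["stable"].state_indices == kept

    def test_fas_variant_unstable_states_include_the_niche_profiles(
        self, root_grn_fas0
    ):
        m = Model(root_grn_fas0, "async")
        stable, unstable = steady_state_report(m)
        steady = stable | unstable
        for profile in TABLE2_PROFILES.values():
            assert profile_index(root_grn_fas0, profile) in steady


class TestTerminalAttractors:
    def test_cycle_formula_picks_up_nonterminal_cycles_terminal_scc_does_not(self):
        # A self-loop that can escape into a sink: on a cycle, not terminal
        g = parse_equations("A := A; A := 1; B := A;")
        m = Model(g, "async", "explicit")
        att = attractor_states(m)
        terms = terminal_attractors(m)
        term_states = set()
        for t in terms:
            term_states |= set(t.indices())
        assert term_states <= set(att.indices())
        assert set(att.indices()) - term_states  # strictly more cycle states

    def test_root_network_has_seven_terminal_singletons(self, root_grn):
        m = Model(root_grn, "async")
        terms = terminal_attractors(m)
        assert len(terms) == 7
        assert all(len(t) == 1 for t in terms)


class TestQueryResult:
    def test_round_trip_and_cap(self, root_grn):
        m = Model(root_grn, "async")
        stable, _ = steady_state_report(m)
        res = query_result(m, "stable", stable, "down s . AX s", cap=3)
        assert res.count == 7 and len(res.state_indices) == 3 and res.capped
        payload = json.loads(res.to_json())
        assert payload["count"] == 7
        # enumerated rows decode to member states
        for idx, row in zip(res.state_indices, res.states):
            assert encode([row[n] for n in root_grn.names]) == idx

    def test_tsv_has_one_gene_per_column(self, root_grn):
        m = Model(root_grn, "async")
        res = query_result(m, "x", m.rel.singleton(431), "#431")
        header, row = res.to_tsv().strip().split("\n")
        assert header.split("\t") == ["state_index", *root_grn.names]
        assert row.split("\t")[0] == "431"
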