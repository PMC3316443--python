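"""Transition construction, the state-set algebra and backend agreement."""

from math import prod

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnmc.network import parse_equations
from grnmc.random_nets import random_grn
from grnmc.statespace import (
    build_transitions,
    decode,
    edges_tsv,
    encode,
    out_degree_at_least,
)

BACKENDS = ["explicit", "symbolic"]


def test_state_numbering_follows_lexicographic_gene_order():
    # first gene in lexicographic order is the most significant bit
    assert encode((1, 0, 0)) == 4
    assert encode((0, 0, 1)) == 1
    for idx in range(8):
        assert encode(decode(idx, 3)) == idx


@pytest.mark.parametrize("backend", BACKENDS)
class TestConstruction:
    def test_deterministic_synchronous_is_a_function(self, backend):
        rel = build_transitions(parse_equations("A := B; B := A;"), "sync", backend)
        assert rel.successors(encode((0, 1))).indices() == (encode((1, 0)),)
        assert rel.num_transitions == rel.num_states

    def test_asynchronous_branching_without_self_loop(self, backend):
        # both genes must change: two interleavings, no self-loop
        rel = build_transitions(parse_equations("A := B; B := A;"), "async", backend)
        succ = rel.successors(encode((0, 1)))
        assert set(succ.indices()) == {encode((1, 1)), encode((0, 0))}

    def test_fixed_points_self_loop_in_both_modes(self, backend):
        g = parse_equations("A := A; B := A & B;")
        for mode in ("sync", "async"):
            rel = build_transitions(g, mode, backend)
            fp = encode((1, 1))
            assert fp in rel.successors(fp)

    def test_indeterminate_hold_gives_self_loop_plus_exit(self, backend):
        rel = build_transitions(parse_equations("A := A; A := ~A;"), "async", backend)
        for s in (0, 1):
            assert set(rel.successors(s).indices()) == {0, 1}

    def test_preimage_postimage_and_totality(self, backend, root_grn):
        rel = build_transitions(root_grn, "async", backend)
        full, empty = rel.full(), rel.empty()
        assert rel.preimage(full) == full  # totality
        assert rel.preimage(empty) == empty
        # chain (0,0) -> (1,0) -> (1,1) -> (1,1): preimage of the sink is
        # the sink and its immediate predecessor
        chain = build_transitions(
            parse_equations("A := 1; B := A;"), "sync", backend
        )
        sink = encode((1, 1))
        pre = chain.preimage(chain.singleton(sink))
        assert set(pre.indices()) == {encode((1, 0)), sink}

    def test_set_algebra_laws(self, backend, root_grn):
        rel = build_transitions(root_grn, "async", backend)
        x = rel.gene_true("SCR")
        y = rel.gene_true("WOX")
        assert ~(~x) == x
        assert len(x | y) + len(x & y) == len(x) + len(y)
        assert (x - y) == (x & ~y)
        assert len(rel.full()) == 512 and len(rel.empty()) == 0


class TestOutDegree:
    def test_deterministic_sync_has_no_branching(self):
        rel = build_transitions(parse_equations("A := B; B := A;"), "sync", "explicit")
        assert len(out_degree_at_least(rel, 2)) == 0
        assert out_degree_at_least(rel, 1) == rel.full()

    @pytest.mark.parametrize("backend", BACKENDS)
    def test_star_row_states_branch(self, backend, root_grn_star):
        # every state matching the indeterminate SCR row gains a branch
        rel = build_transitions(root_grn_star, "async", backend)
        multi = rel.out_degree_at_least(2)
        star_states = (
            rel.gene_true("SHR")
            & rel.gene_true("SCR")
            & ~rel.gene_true("JKD")
            & rel.gene_true("MGP")
        )
        assert len(star_states) == 32
        assert star_states.issubset(multi)

    def test_scan_touches_each_state_and_transition_once(self, root_grn):
        rel = build_transitions(root_grn, "async", "explicit")
        rel.out_degree_at_least(2)
        assert rel.last_scan == {
            "states": rel.num_states,
            "edges": rel.num_transitions,
        }


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(1, 6),
    k=st.integers(1, 3),
    star=st.sampled_from([0.0, 0.2]),
    seed=st.integers(0, 10_000),
    mode=st.sampled_from(["sync", "async"]),
)
def test_relations_are_total_on_random_networks(n, k, star, seed, mode):
    g = random_grn(n, k, star, seed=seed)
    rel = build_transitions(g, mode, "explicit")
    assert all(rel.succs[s] for s in range(rel.num_states))
    if mode == "sync":
        from itertools import product as iproduct

        for s in range(rel.num_states):
            env = g.env_of(decode(s, n))
            expected = prod(len(g.rules[name].allowed(env)) for name in g.names)
            assert len(rel.succs[s]) == expected
    else:
        for s, t in rel.edges():
            assert bin(s ^ t).count("1") <= 1  # at most one gene changes


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    n=st.integers(1, 6),
    seed=st.integers(0, 10_000),
    star=st.sampled_from([0.0, 0.2]),
    mode=st.sampled_from(["sync", "async"]),
)
def test_backends_agree_edge_for_edge(n, seed, star, mode):
    g = random_grn(n, 2, star, seed=seed)
    exp = build_transitions(g, mode, "explicit")
    sym = build_transitions(g, mode, "symbolic")
    assert sorted(exp.edges()) == sorted(sym.edges())
    x_exp = exp.gene_true(g.names[0])
    x_sym = sym.gene_true(g.names[0])
    assert exp.preimage(x_exp).indices() == sym.preimage(x_sym).indices()
    assert exp.postimage(x_exp).indices() == sym.postimage(x_sym).indices()
    assert exp.self_loop_states().indices() == sym.self_loop_states().indices()
    assert exp.two_cycle_states().indices() == sym.two_cycle_states().indices()


def test_edge_list_export_is_sorted_tsv(root_grn):
    rel = build_transitions(parse_equations("A := B; B := A;"), "sync", "explicit")
    text = edges_tsv(rel)
    lines = text.strip().split("\n")
    assert lines[0] == "source_index\ttarget_index"
    assert lines[1:] == ["0\t0", "1\t2", "2\t1", "3\t3"]
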