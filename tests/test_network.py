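"""Parsing, validation and rewriting of networks in both dialects."""

from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnmc.errors import DialectSyntaxError, UnknownGeneError
from grnmc.fixtures import TABLE2_PROFILES
from grnmc.network import (
    parse_equations,
    parse_network,
    parse_tables,
    rule_as_bodies,
    rule_as_table,
)
from grnmc.random_nets import random_grn
from grnmc.statespace import build_transitions

TABLE3 = """\
target SCR : SHR SCR JKD MGP;
0 0 0 0 : 0
0 0 0 1 : 0
0 0 1 0 : 0
0 0 1 1 : 0
0 1 0 0 : 0
0 1 0 1 : 0
0 1 1 0 : 0
0 1 1 1 : 0
1 0 0 0 : 0
1 0 0 1 : 0
1 0 1 0 : 0
1 0 1 1 : 0
1 1 0 0 : 1
1 1 0 1 : *
1 1 1 0 : 1
1 1 1 1 : 1
target SHR;
: 1
target JKD;
: 0
target MGP;
: 0
"""


def all_states(n):
    return product((0, 1), repeat=n)


class TestEquationDialect:
    def test_root_model_has_nine_single_body_rules(self, root_grn):
        assert root_grn.n == 9
        assert root_grn.names == (
            "ARF", "AUXINS", "IAA", "JKD", "MGP", "PLT", "SCR", "SHR", "WOX",
        )
        assert all(
            len(root_grn.rules[g].bodies) == 1 for g in root_grn.names
        )
        assert root_grn.is_deterministic()

    def test_identity_rule_persists_current_value(self):
        g = parse_equations("A := A;")
        assert g.allowed_next_values((0,), "A") == {0}
        assert g.allowed_next_values((1,), "A") == {1}

    def test_duplicate_lhs_merges_into_indeterminate_rule(self):
        g = parse_equations("A := B; A := ~B; B := A;")
        assert len(g.rules["A"].bodies) == 2
        # the two bodies disagree at every state: A is always indeterminate
        for vals in all_states(2):
            assert g.allowed_next_values(vals, "A") == {0, 1}
            assert len(g.allowed_next_values(vals, "B")) == 1

    def test_printed_colon_space_equals_variant_accepted(self):
        g = parse_equations("PLT: = ARF;\nARF := PLT;")
        assert set(g.names) == {"ARF", "PLT"}

    def test_comments_and_precedence(self):
        g = parse_equations(
            "// tilde binds tighter than & which binds tighter than |\n"
            "A := ~ B & C | A;\nB := B;\nC := C;"
        )
        for vals in all_states(3):
            a, b, c = vals
            expected = ((1 - b) & c) | a
            assert g.allowed_next_values(vals, "A") == {expected}

    def test_undeclared_gene_is_an_error(self):
        with pytest.raises(UnknownGeneError, match="unknown gene 'B'"):
            parse_equations("A := B;")

    @pytest.mark.parametrize(
        "text", ["", "   \n// only a comment\n", "A := ;", "A := B |;  B := A;", "A B;"]
    )
    def test_syntax_errors_are_rejected(self, text):
        with pytest.raises((DialectSyntaxError, UnknownGeneError)):
            parse_equations(text)


class TestTableDialect:
    def test_table3_star_row_gives_both_values(self):
        g = parse_tables(TABLE3)
        vals = {name: 0 for name in g.names}
        vals.update(SHR=1, SCR=1, JKD=0, MGP=1)
        state = tuple(vals[name] for name in g.names)
        assert g.allowed_next_values(state, "SCR") == {0, 1}
        assert sum(o == "*" for o in g.rules["SCR"].outputs) == 1

    def test_star_to_zero_resolution_equals_printed_equation(self):
        flat = parse_tables(TABLE3.replace(": *", ": 0"))
        eq = parse_equations(
            "SCR := SHR & SCR & (JKD | ~ MGP);"
            "SHR := SHR; JKD := JKD; MGP := MGP;"
        )
        for vals in all_states(4):
            env = dict(zip(flat.names, vals))
            state_eq = tuple(env[n] for n in eq.names)
            assert flat.allowed_next_values(vals, "SCR") == eq.allowed_next_values(
                state_eq, "SCR"
            )

    def test_zero_regulator_table_is_constant(self):
        g = parse_tables("target A;\n: 1\ntarget B : A;\n0 : 0\n1 : 1\n")
        for vals in all_states(2):
            assert g.allowed_next_values(vals, "A") == {1}

    @pytest.mark.parametrize(
        "mangle",
        [
            lambda t: t.replace("1 1 1 1 : 1\n", "", 1),  # missing row
            lambda t: t.replace("0 0 0 0 : 0\n", "0 0 0 0 : 0\n0 0 0 0 : 0\n"),
            lambda t: t.replace(": *", ": 2"),  # bad output symbol
            lambda t: t.replace("1 1 0 1 : *\n", "1 1 0 : *\n"),  # short row
        ],
    )
    def test_malformed_tables_are_rejected(self, mangle):
        with pytest.raises(DialectSyntaxError):
            parse_tables(mangle(TABLE3))

    def test_dialect_autodetection(self, root_grn, root_grn_star):
        from grnmc.fixtures import fixture_text

        assert parse_network(fixture_text("root_scn.eq")).names == root_grn.names
        assert (
            parse_network(fixture_text("root_scn_scr_star.tables")).names
            == root_grn_star.names
        )


class TestPerturb:
    def test_clamp_is_constant_everywhere(self, root_grn):
        lof = root_grn.perturb("JKD", 0)
        for vals in [(0,) * 9, (1,) * 9, (1, 0) * 4 + (1,)]:
            assert lof.allowed_next_values(vals, "JKD") == {0}
        # other rules untouched
        assert lof.rules["SCR"] is root_grn.rules["SCR"]

    def test_last_clamp_wins(self):
        g = parse_equations("A := A;").perturb("A", 1).perturb("A", 0)
        assert g.allowed_next_values((1,), "A") == {0}

    def test_unknown_gene_rejected(self, root_grn):
        with pytest.raises(UnknownGeneError):
            root_grn.perturb("FAS", 0)

    def test_shr_knockout_leaves_single_auxin_active_stable_state(self, root_grn):
        rel = build_transitions(root_grn.perturb("SHR", 0), "async", "explicit")
        stable = {
            s
            for s in range(512)
            if rel.succs[s] == frozenset((s,))
        }
        aux = rel.gene_true("AUXINS")
        assert sum(1 for s in stable if s in aux) == 1


class TestRoundTripsAndConversions:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 5),
        k=st.integers(1, 3),
        star=st.sampled_from([0.0, 0.3]),
        seed=st.integers(0, 10_000),
    )
    def test_serialize_reparse_preserves_rule_function(self, n, k, star, seed):
        g = random_grn(n, k, star, seed=seed)
        for text, parser in [
            (g.to_tables_text(), parse_tables),
            (g.to_equations_text(), parse_equations),
        ]:
            h = parser(text)
            assert h.names == g.names
            for vals in all_states(n):
                for name in g.names:
                    assert g.allowed_next_values(vals, name) == h.allowed_next_values(
                        vals, name
                    )

    def test_equation_to_table_conversion_pointwise(self, root_grn):
        for name in root_grn.names:
            tab = rule_as_table(root_grn.rules[name])
            back = rule_as_bodies(tab)
            for vals in all_states(root_grn.n):
                env = root_grn.env_of(vals)
                assert tab.allowed(env) == root_grn.rules[name].allowed(env)
                assert back.allowed(env) == tab.allowed(env)

    def test_determinism_detection(self, root_grn, root_grn_star):
        assert root_grn.is_deterministic()
        assert not root_grn_star.is_deterministic()
        assert not parse_equations("A := A; A := ~A;").is_deterministic()

    def test_json_export_mentions_every_gene(self, root_grn_star):
        import json

        payload = json.loads(root_grn_star.to_json())
        assert payload["genes"] == list(root_grn_star.names)
        targets = {r["target"] for r in payload["rules"]}
        assert targets == set(root_grn_star.names)
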