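"""Boolean gene regulatory networks with indeterminations.

A network (:class:`GRN`) assigns every gene one update rule. A rule is
either a set of Boolean expression *bodies* (equation dialect — several
bodies for the same gene encode an indetermination: the allowed next values
are the union of the bodies' values) or a complete truth table over a
declared regulator list whose outputs are ``0``, ``1`` or ``*`` (table
dialect — ``*`` allows both next values).

Genes are kept in canonical order: ASCII-lexicographic ascending by name.
State numbering elsewhere in the package derives from this order.

Equation dialect::

    // comment to end of line
    SCR := SHR & SCR & (JKD | ~ MGP);
    A := B;  A := ~ B;              // two bodies: indetermination

``:=`` may be written ``: =``; operators are ``~ & |`` with precedence
``~`` > ``&`` > ``|``; ``0``/``1`` are constant atoms. Every referenced
name must have an equation of its own.

Table dialect::

    target SCR : SHR SCR JKD MGP;
    0 0 0 0 : 0
    ...
    1 1 0 1 : *
    ...

One header per gene, then exactly ``2^k`` rows, one per regulator-value
combination (any row order), each ``b1 .. bk : o`` with ``o`` in ``0 1 *``.
A regulator-free gene is written ``target A;`` with the single row ``: 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

from ._expr import AndE, Const, Expr, NotE, OrE, Ref
from .errors import DialectSyntaxError, UnknownGeneError

__all__ = [
    "Gene",
    "Rule",
    "GRN",
    "parse_equations",
    "parse_tables",
    "parse_network",
    "grn_from_rules",
    "allowed_next_values",
    "perturb",
]


@dataclass(frozen=True)
class Gene:
    """A named node of the network; ``index`` is its canonical position."""

    name: str
    index: int


@dataclass(frozen=True)
class Rule:
    """Update rule for one gene.

    Exactly one of the two representations is populated:

    * ``bodies`` — tuple of expression trees (equation dialect);
    * ``regulators``/``outputs`` — truth table (table dialect), where
      ``outputs[r]`` is the output character for the row whose regulator
      bits, first regulator most significant, encode the integer ``r``.
    """

    target: str
    bodies: tuple[Expr, ...] = ()
    regulators: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()

    @property
    def is_table(self) -> bool:
        return bool(self.outputs)

    def refs(self) -> frozenset[str]:
        if self.is_table:
            return frozenset(self.regulators)
        out: frozenset[str] = frozenset()
        for b in self.bodies:
            out |= b.refs()
        return out

    def allowed(self, env: Mapping[str, int]) -> frozenset[int]:
        """Allowed next values of the target in the state ``env`` (never empty)."""
        if self.is_table:
            row = 0
            for name in self.regulators:
                row = (row << 1) | env[name]
            o = self.outputs[row]
            if o == "*":
                return _BOTH
            return _ONE if o == "1" else _ZERO
        return frozenset(b.eval(env) for b in self.bodies)


_ZERO = frozenset((0,))
_ONE = frozenset((1,))
_BOTH = frozenset((0, 1))


class GRN:
    """An ordered gene list plus one rule per gene."""

    def __init__(self, rules: Mapping[str, Rule]):
        if not rules:
            raise UnknownGeneError("a network must declare at least one gene")
        names = sorted(rules)
        self.genes: tuple[Gene, ...] = tuple(
            Gene(name, i) for i, name in enumerate(names)
        )
        self.rules: dict[str, Rule] = {name: rules[name] for name in names}
        self._index = {g.name: g.index for g in self.genes}
        for rule in self.rules.values():
            for ref in rule.refs():
                if ref not in self.rules:
                    raise UnknownGeneError(
                        f"unknown gene {ref!r} referenced by rule for {rule.target!r}"
                    )

    # -- basic queries ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise UnknownGeneError(f"unknown gene {name!r}") from None

    def env_of(self, values: Sequence[int]) -> dict[str, int]:
        return {g.name: values[g.index] for g in self.genes}

    def allowed_next_values(self, values: Sequence[int], gene: str) -> frozenset[int]:
        """Allowed next values of ``gene`` when the network is in state ``values``
        (bits in canonical gene order)."""
        rule = self.rules.get(gene)
        if rule is None:
            raise UnknownGeneError(f"unknown gene {gene!r}")
        return rule.allowed(self.env_of(values))

    def is_deterministic(self) -> bool:
        """True iff no (state, gene) pair admits more than one next value."""
        for values in product((0, 1), repeat=self.n):
            env = self.env_of(values)
            for rule in self.rules.values():
                if len(rule.allowed(env)) > 1:
                    return False
        return True

    # -- rewriting -------------------------------------------------------
    def perturb(self, gene: str, clamp: int) -> "GRN":
        """Copy of the network with ``gene`` clamped to the constant ``clamp``
        (0 = loss of function, 1 = gain of function)."""
        if gene not in self.rules:
            raise UnknownGeneError(f"unknown gene {gene!r}")
        if clamp not in (0, 1):
            raise ValueError("clamp must be 0 or 1")
        rules = dict(self.rules)
        rules[gene] = Rule(target=gene, bodies=(Const(clamp),))
        return GRN(rules)

    # -- serialization ---------------------------------------------------
    def to_equations_text(self) -> str:
        """Render as the equation dialect (table rules are converted)."""
        lines = []
        for g in self.genes:
            rule = self.rules[g.name]
            for body in rule_bodies(rule):
                lines.append(f"{g.name} := {body.to_text()};")
        return "\n".join(lines) + "\n"

    def to_tables_text(self) -> str:
        """Render as the table dialect (equation rules are converted)."""
        blocks = []
        for g in self.genes:
            blocks.append(_table_block(rule_as_table(self.rules[g.name])))
        return "\n".join(blocks)

    def to_json(self) -> str:
        payload = {
            "genes": list(self.names),
            "rules": [
                (
                    {
                        "target": g.name,
                        "regulators": list(self.rules[g.name].regulators),
                        "table": "".join(self.rules[g.name].outputs),
                    }
                    if self.rules[g.name].is_table
                    else {
                        "target": g.name,
                        "bodies": [b.to_text() for b in self.rules[g.name].bodies],
                    }
                )
                for g in self.genes
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# module-level operation wrappers


def allowed_next_values(grn: GRN, values: Sequence[int], gene: str) -> frozenset[int]:
    return grn.allowed_next_values(values, gene)


def perturb(grn: GRN, gene: str, clamp: int) -> GRN:
    return grn.perturb(gene, clamp)


def grn_from_rules(rules: Iterable[Rule]) -> GRN:
    """Build a network from rules produced programmatically."""
    table: dict[str, Rule] = {}
    for rule in rules:
        if rule.target in table:
            prev = table[rule.target]
            if prev.is_table or rule.is_table:
                raise UnknownGeneError(
                    f"gene {rule.target!r} has more than one table rule"
                )
            table[rule.target] = Rule(
                target=rule.target, bodies=prev.bodies + rule.bodies
            )
        else:
            table[rule.target] = rule
    return GRN(table)


# ---------------------------------------------------------------------------
# rule conversions (equation <-> table)


def rule_as_table(rule: Rule) -> Rule:
    """Equivalent table rule; regulators are the referenced genes in
    canonical (lexicographic) order."""
    if rule.is_table:
        return rule
    regulators = tuple(sorted(rule.refs()))
    k = len(regulators)
    outputs = []
    for bits in product((0, 1), repeat=k):
        env = dict(zip(regulators, bits))
        vals = frozenset(b.eval(env) for b in rule.bodies)
        outputs.append("*" if len(vals) == 2 else ("1" if 1 in vals else "0"))
    return Rule(target=rule.target, regulators=regulators, outputs=tuple(outputs))


def rule_as_bodies(rule: Rule) -> Rule:
    """Equivalent equation rule: one body if the table has no stars, else two
    (star rows are exactly where the bodies disagree)."""
    if not rule.is_table:
        return rule
    ones = _minterms(rule, "1")
    stars_or_ones = _minterms(rule, "1*")
    if "*" in rule.outputs:
        return Rule(target=rule.target, bodies=(ones, stars_or_ones))
    return Rule(target=rule.target, bodies=(ones,))


def rule_bodies(rule: Rule) -> tuple[Expr, ...]:
    return rule_as_bodies(rule).bodies


def _minterms(rule: Rule, chars: str) -> Expr:
    k = len(rule.regulators)
    terms: list[Expr] = []
    for row, out in enumerate(rule.outputs):
        if out not in chars:
            continue
        cube: Expr | None = None
        for j, name in enumerate(rule.regulators):
            bit = (row >> (k - 1 - j)) & 1
            lit: Expr = Ref(name) if bit else NotE(Ref(name))
            cube = lit if cube is None else AndE(cube, lit)
        terms.append(cube if cube is not None else Const(1))
    if not terms:
        return Const(0)
    expr = terms[0]
    for t in terms[1:]:
        expr = OrE(expr, t)
    return expr


def _table_block(rule: Rule) -> str:
    head = f"target {rule.target}"
    if rule.regulators:
        head += " : " + " ".join(rule.regulators)
    lines = [head + ";"]
    k = len(rule.regulators)
    for row, out in enumerate(rule.outputs):
        bits = " ".join(str((row >> (k - 1 - j)) & 1) for j in range(k))
        lines.append(f"{bits} : {out}".lstrip())
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# equation dialect parser


_SYMBOLS = (":=", "(", ")", "&", "|", "~", ";")


def _tokenize(text: str) -> list[tuple[str, str, int, int]]:
    """Tokens are (kind, value, line, column); kind is 'name', 'num' or 'sym'."""
    tokens = []
    i, line, col = 0, 1, 1
    n = len(text)
    while i < n:
        c = text[i]
        if c == "\n":
            i += 1
            line += 1
            col = 1
            continue
        if c.isspace():
            i += 1
            col += 1
            continue
        if text.startswith("//", i):
            while i < n and text[i] != "\n":
                i += 1
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(("name", text[i:j], line, col))
            col += j - i
            i = j
            continue
        if c in "01" and not (i + 1 < n and (text[i + 1].isalnum() or text[i + 1] == "_")):
            tokens.append(("num", c, line, col))
            i += 1
            col += 1
            continue
        if c == ":":
            # accept ':=' and the printed variant ': ='
            j = i + 1
            extra = 0
            while j < n and text[j] in " \t":
                j += 1
                extra += 1
            if j < n and text[j] == "=":
                tokens.append(("sym", ":=", line, col))
                i = j + 1
                col += 2 + extra
                continue
            tokens.append(("sym", ":", line, col))
            i += 1
            col += 1
            continue
        if c in "()&|~;*=":
            tokens.append(("sym", c, line, col))
            i += 1
            col += 1
            continue
        raise DialectSyntaxError(f"unexpected character {c!r}", line, col)
    tokens.append(("eof", "", line, col))
    return tokens


class _EqParser:
    def __init__(self, text: str):
        self.toks = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.toks[self.pos]

    def take(self):
        t = self.toks[self.pos]
        self.pos += 1
        return t

    def fail(self, msg: str):
        _, _, line, col = self.peek()
        raise DialectSyntaxError(msg, line, col)

    def expect(self, value: str):
        kind, val, _, _ = self.peek()
        if val != value:
            self.fail(f"expected {value!r}, found {val or 'end of file'!r}")
        return self.take()

    def parse(self) -> GRN:
        bodies: dict[str, list[Expr]] = {}
        order_seen: list[str] = []
        if self.peek()[0] == "eof":
            self.fail("empty network description")
        while self.peek()[0] != "eof":
            kind, val, _, _ = self.peek()
            if kind != "name":
                self.fail(f"expected a gene name, found {val!r}")
            name = self.take()[1]
            self.expect(":=")
            expr = self.parse_or()
            self.expect(";")
            bodies.setdefault(name, []).append(expr)
            if name not in order_seen:
                order_seen.append(name)
        rules = {
            name: Rule(target=name, bodies=tuple(bs)) for name, bs in bodies.items()
        }
        try:
            return GRN(rules)
        except UnknownGeneError as exc:
            raise UnknownGeneError(str(exc)) from None

    # precedence: ~ > & > |
    def parse_or(self) -> Expr:
        e = self.parse_and()
        while self.peek()[1] == "|":
            self.take()
            e = OrE(e, self.parse_and())
        return e

    def parse_and(self) -> Expr:
        e = self.parse_unary()
        while self.peek()[1] == "&":
            self.take()
            e = AndE(e, self.parse_unary())
        return e

    def parse_unary(self) -> Expr:
        kind, val, _, _ = self.peek()
        if val == "~":
            self.take()
            return NotE(self.parse_unary())
        if val == "(":
            self.take()
            e = self.parse_or()
            self.expect(")")
            return e
        if kind == "name":
            return Ref(self.take()[1])
        if kind == "num":
            return Const(int(self.take()[1]))
        self.fail(f"expected an expression, found {val or 'end of file'!r}")
        raise AssertionError  # unreachable


def parse_equations(text: str) -> GRN:
    """Parse the equation dialect; duplicate left-hand sides merge into a
    multi-body (indeterminate) rule."""
    return _EqParser(text).parse()


# ---------------------------------------------------------------------------
# table dialect parser


def parse_tables(text: str) -> GRN:
    """Parse the table dialect; ``*`` outputs denote indeterminations."""
    lines = text.split("\n")
    rules: dict[str, Rule] = {}
    current: dict | None = None

    def finish(lineno: int):
        nonlocal current
        if current is None:
            return
        k = len(current["regulators"])
        rows: dict[int, str] = current["rows"]
        if len(rows) != 2**k:
            missing = next(r for r in range(2**k) if r not in rows)
            bits = " ".join(str((missing >> (k - 1 - j)) & 1) for j in range(k))
            raise DialectSyntaxError(
                f"table for {current['target']!r} has {len(rows)} rows, "
                f"expected {2 ** k} (missing row {bits!r})",
                lineno,
                1,
            )
        name = current["target"]
        if name in rules:
            raise DialectSyntaxError(f"duplicate table for gene {name!r}", lineno, 1)
        rules[name] = Rule(
            target=name,
            regulators=tuple(current["regulators"]),
            outputs=tuple(rows[r] for r in range(2**k)),
        )
        current = None

    for lineno, raw in enumerate(lines, start=1):
        stripped = raw.split("//", 1)[0].strip()
        if not stripped:
            continue
        if stripped.startswith("target"):
            finish(lineno)
            head = stripped.rstrip(";").removeprefix("target").strip()
            if ":" in head:
                name, _, regs = head.partition(":")
                regulators = regs.split()
            else:
                name, regulators = head, []
            name = name.strip()
            if not name:
                raise DialectSyntaxError("missing target gene name", lineno, 1)
            if len(set(regulators)) != len(regulators):
                raise DialectSyntaxError(
                    f"duplicated regulator in table for {name!r}", lineno, 1
                )
            current = {"target": name, "regulators": regulators, "rows": {}}
            continue
        if current is None:
            raise DialectSyntaxError(
                f"row {stripped!r} appears before any 'target' header", lineno, 1
            )
        ins, sep, out = stripped.partition(":")
        if not sep:
            raise DialectSyntaxError(f"missing ':' in row {stripped!r}", lineno, 1)
        bits = ins.split()
        out = out.strip()
        k = len(current["regulators"])
        if len(bits) != k or any(b not in ("0", "1") for b in bits):
            raise DialectSyntaxError(
                f"row must have {k} input bits, got {ins.strip()!r}", lineno, 1
            )
        if out not in ("0", "1", "*"):
            raise DialectSyntaxError(
                f"output must be 0, 1 or *, got {out!r}", lineno, 1
            )
        row = 0
        for b in bits:
            row = (row << 1) | int(b)
        if row in current["rows"]:
            raise DialectSyntaxError(f"duplicated row {ins.strip()!r}", lineno, 1)
        current["rows"][row] = out
    finish(len(lines))
    if not rules:
        raise DialectSyntaxError("empty network description", max(1, len(lines)), 1)
    return GRN(rules)


def parse_network(text: str, dialect: str = "auto") -> GRN:
    """Parse either dialect; ``auto`` sniffs for a ``target`` header."""
    if dialect == "equations":
        return parse_equations(text)
    if dialect == "tables":
        return parse_tables(text)
    if dialect != "auto":
        raise ValueError(f"unknown dialect {dialect!r}")
    for raw in text.split("\n"):
        stripped = raw.split("//", 1)[0].strip()
        if not stripped:
            continue
        if stripped.startswith("target"):
            return parse_tables(text)
        return parse_equations(text)
    return parse_equations(text)  # empty: let the parser raise
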