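"""Formula ASTs and the parser for CTL + hybrid state variables + EY.

Grammar (ASCII)::

    f  :=  f1 ('->' | 'implies') f        (right-associative, weakest)
    f1 :=  f2 (('or' | '|') f2)*
    f2 :=  f3 (('and' | '&') f3)*
    f3 :=  ('not' | '~') f3
        |  EX f3 | AX f3 | EF f3 | AF f3 | EG f3 | AG f3 | EY f3
        |  E '[' f 'U' f ']'  |  A '[' f 'U' f ']'
        |  down NAME '.' f                 (the binder body extends right)
        |  true | false | '#' INT | NAME | '(' f ')'

Names are shared between gene atoms and state variables; a name evaluates
as the state bound by the innermost enclosing ``down`` of that name, and as
a gene atom otherwise (so a binder shadows a like-named gene). ``#k`` is
the literal for the state whose index is ``k`` in the lexicographic-binary
numbering. ``E`` and ``A`` are only special before ``[``, so genes named
``E`` or ``A`` remain usable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from functools import lru_cache

from .errors import FormulaSyntaxError

__all__ = [
    "Formula",
    "TrueF",
    "FalseF",
    "Name",
    "StateLit",
    "Not",
    "And",
    "Or",
    "Implies",
    "EX",
    "AX",
    "EF",
    "AF",
    "EG",
    "AG",
    "EY",
    "EU",
    "AU",
    "Bind",
    "parse_formula",
    "free_vars",
    "rewrite_derived",
    "pretty",
    "alpha_equal",
    "ast_json",
]


class Formula:
    """Base class of all formula nodes (immutable, hashable)."""

    __slots__ = ()


@dataclass(frozen=True)
class TrueF(Formula):
    pass


@dataclass(frozen=True)
class FalseF(Formula):
    pass


@dataclass(frozen=True)
class Name(Formula):
    """A gene atom or a state variable, disambiguated by binding."""

    name: str


@dataclass(frozen=True)
class StateLit(Formula):
    """``#k`` — the singleton of the state with index ``k``."""

    index: int


@dataclass(frozen=True)
class Not(Formula):
    child: Formula


@dataclass(frozen=True)
class And(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Or(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Implies(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class EX(Formula):
    child: Formula


@dataclass(frozen=True)
class AX(Formula):
    child: Formula


@dataclass(frozen=True)
class EF(Formula):
    child: Formula


@dataclass(frozen=True)
class AF(Formula):
    child: Formula


@dataclass(frozen=True)
class EG(Formula):
    child: Formula


@dataclass(frozen=True)
class AG(Formula):
    child: Formula


@dataclass(frozen=True)
class EY(Formula):
    """Exists Yesterday — some predecessor satisfies the operand."""

    child: Formula


@dataclass(frozen=True)
class EU(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class AU(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Bind(Formula):
    """``down var . body`` — binds ``var`` to the evaluation state."""

    var: str
    body: Formula


_UNARY = {"EX": EX, "AX": AX, "EF": EF, "AF": AF, "EG": EG, "AG": AG, "EY": EY}

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<lit>\#\d+)"
    r"|(?P<sym>->|[()\[\].~&|]))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            tail = text[pos:].lstrip()
            if not tail:
                break
            at = len(text) - len(tail)
            raise FormulaSyntaxError(f"unexpected character {tail[0]!r}", at)
        if m.lastgroup == "name":
            tokens.append(("name", m.group("name"), m.start("name")))
        elif m.lastgroup == "lit":
            tokens.append(("lit", m.group("lit"), m.start("lit")))
        else:
            tokens.append(("sym", m.group("sym"), m.start("sym")))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
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
        raise FormulaSyntaxError(msg, self.peek()[2])

    def expect(self, value: str):
        kind, val, _ = self.peek()
        if val != value:
            self.fail(f"expected {value!r}, found {val or 'end of input'!r}")
        return self.take()

    def parse(self) -> Formula:
        f = self.implies()
        if self.peek()[0] != "eof":
            self.fail(f"unexpected trailing {self.peek()[1]!r}")
        return f

    def implies(self) -> Formula:
        left = self.disj()
        kind, val, _ = self.peek()
        if val in ("->", "implies"):
            self.take()
            return Implies(left, self.implies())
        return left

    def disj(self) -> Formula:
        f = self.conj()
        while self.peek()[1] in ("or", "|"):
            self.take()
            f = Or(f, self.conj())
        return f

    def conj(self) -> Formula:
        f = self.unary()
        while self.peek()[1] in ("and", "&"):
            self.take()
            f = And(f, self.unary())
        return f

    def unary(self) -> Formula:
        kind, val, _ = self.peek()
        if val in ("not", "~"):
            self.take()
            return Not(self.unary())
        if kind == "name" and val in _UNARY:
            self.take()
            return _UNARY[val](self.unary())
        if kind == "name" and val in ("E", "A") and self.toks[self.pos + 1][1] == "[":
            self.take()
            self.expect("[")
            left = self.implies()
            k2, v2, _ = self.peek()
            if k2 != "name" or v2 != "U":
                self.fail(f"expected 'U', found {v2 or 'end of input'!r}")
            self.take()
            right = self.implies()
            self.expect("]")
            return EU(left, right) if val == "E" else AU(left, right)
        if val == "down":
            self.take()
            k2, var, _ = self.peek()
            if k2 != "name":
                self.fail("expected a state-variable name after 'down'")
            self.take()
            self.expect(".")
            return Bind(var, self.implies())
        return self.atom()

    def atom(self) -> Formula:
        kind, val, _ = self.peek()
        if val == "(":
            self.take()
            f = self.implies()
            self.expect(")")
            return f
        if val == "true":
            self.take()
            return TrueF()
        if val == "false":
            self.take()
            return FalseF()
        if kind == "lit":
            self.take()
            return StateLit(int(val[1:]))
        if kind == "name":
            return Name(self.take()[1])
        self.fail(f"expected a formula, found {val or 'end of input'!r}")
        raise AssertionError  # unreachable


def parse_formula(text: str) -> Formula:
    if not text.strip():
        raise FormulaSyntaxError("empty formula", 0)
    return _Parser(text).parse()


# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _free_names(f: Formula) -> frozenset[str]:
    if isinstance(f, Name):
        return frozenset((f.name,))
    if isinstance(f, (TrueF, FalseF, StateLit)):
        return frozenset()
    if isinstance(f, Bind):
        return _free_names(f.body) - {f.var}
    if isinstance(f, (Not, EX, AX, EF, AF, EG, AG, EY)):
        return _free_names(f.child)
    return _free_names(f.left) | _free_names(f.right)


def free_vars(f: Formula, genes: frozenset[str] | set[str] = frozenset()) -> frozenset[str]:
    """Names not captured by any enclosing ``down`` and not known genes.

    A formula is closed for a model iff this is empty given the model's
    gene names.
    """
    return _free_names(f) - frozenset(genes)


def rewrite_derived(f: Formula) -> Formula:
    """Eliminate derived operators: AX/AG/AF/AU via their E-dualities and
    ``implies`` via not/or. Idempotent; the primitives afterwards are atoms,
    literals, not/and/or, EX, EY, EF, EG, EU and the binder."""
    if isinstance(f, (TrueF, FalseF, Name, StateLit)):
        return f
    if isinstance(f, Not):
        return Not(rewrite_derived(f.child))
    if isinstance(f, And):
        return And(rewrite_derived(f.left), rewrite_derived(f.right))
    if isinstance(f, Or):
        return Or(rewrite_derived(f.left), rewrite_derived(f.right))
    if isinstance(f, Implies):
        return Or(Not(rewrite_derived(f.left)), rewrite_derived(f.right))
    if isinstance(f, EX):
        return EX(rewrite_derived(f.child))
    if isinstance(f, EY):
        return EY(rewrite_derived(f.child))
    if isinstance(f, EF):
        return EF(rewrite_derived(f.child))
    if isinstance(f, EG):
        return EG(rewrite_derived(f.child))
    if isinstance(f, AX):
        return Not(EX(Not(rewrite_derived(f.child))))
    if isinstance(f, AG):
        return Not(EF(Not(rewrite_derived(f.child))))
    if isinstance(f, AF):
        return Not(EG(Not(rewrite_derived(f.child))))
    if isinstance(f, EU):
        return EU(rewrite_derived(f.left), rewrite_derived(f.right))
    if isinstance(f, AU):
        phi = rewrite_derived(f.left)
        psi = rewrite_derived(f.right)
        return Not(
            Or(EU(Not(psi), And(Not(phi), Not(psi))), EG(Not(psi)))
        )
    if isinstance(f, Bind):
        return Bind(f.var, rewrite_derived(f.body))
    raise TypeError(f"unknown formula node {f!r}")


# ---------------------------------------------------------------------------


def pretty(f: Formula) -> str:
    """Render with minimal parentheses; ``parse_formula(pretty(f)) == f``."""
    return _fmt(f, 0)


def _fmt(f: Formula, prec: int) -> str:
    if isinstance(f, TrueF):
        return "true"
    if isinstance(f, FalseF):
        return "false"
    if isinstance(f, Name):
        return f.name
    if isinstance(f, StateLit):
        return f"#{f.index}"
    if isinstance(f, Not):
        return "not " + _fmt(f.child, 4)
    if isinstance(f, (EX, AX, EF, AF, EG, AG, EY)):
        return type(f).__name__ + " " + _fmt(f.child, 4)
    if isinstance(f, And):
        s = f"{_fmt(f.left, 3)} and {_fmt(f.right, 4)}"
        return f"({s})" if prec > 3 else s
    if isinstance(f, Or):
        s = f"{_fmt(f.left, 2)} or {_fmt(f.right, 3)}"
        return f"({s})" if prec > 2 else s
    if isinstance(f, Implies):
        s = f"{_fmt(f.left, 2)} implies {_fmt(f.right, 1)}"
        return f"({s})" if prec > 1 else s
    if isinstance(f, EU):
        return f"E[{_fmt(f.left, 0)} U {_fmt(f.right, 0)}]"
    if isinstance(f, AU):
        return f"A[{_fmt(f.left, 0)} U {_fmt(f.right, 0)}]"
    if isinstance(f, Bind):
        s = f"down {f.var} . {_fmt(f.body, 0)}"
        return f"({s})" if prec > 0 else s
    raise TypeError(f"unknown formula node {f!r}")


def alpha_equal(f: Formula, g: Formula) -> bool:
    """Structural equality up to consistent renaming of bound variables."""
    return _alpha(f, g, {}, {})


def _alpha(f: Formula, g: Formula, fmap: dict, gmap: dict) -> bool:
    if type(f) is not type(g):
        return False
    if isinstance(f, Name):
        fb = fmap.get(f.name)
        gb = gmap.get(g.name)
        if fb is None and gb is None:
            return f.name == g.name  # both free (gene atoms)
        return fb is not None and fb == gb
    if isinstance(f, (TrueF, FalseF)):
        return True
    if isinstance(f, StateLit):
        return f.index == g.index
    if isinstance(f, Bind):
        depth = len(fmap) + 1
        return _alpha(
            f.body, g.body, {**fmap, f.var: depth}, {**gmap, g.var: depth}
        )
    if isinstance(f, (Not, EX, AX, EF, AF, EG, AG, EY)):
        return _alpha(f.child, g.child, fmap, gmap)
    return _alpha(f.left, g.left, fmap, gmap) and _alpha(
        f.right, g.right, fmap, gmap
    )


def ast_json(f: Formula) -> str:
    """Debug export of the AST as JSON."""

    def conv(node: Formula):
        if isinstance(node, (TrueF, FalseF)):
            return {"op": type(node).__name__.rstrip("F").lower()}
        if isinstance(node, Name):
            return {"op": "name", "name": node.name}
        if isinstance(node, StateLit):
            return {"op": "state", "index": node.index}
        if isinstance(node, Bind):
            return {"op": "down", "var": node.var, "body": conv(node.body)}
        if isinstance(node, (Not, EX, AX, EF, AF, EG, AG, EY)):
            return {"op": type(node).__name__.lower(), "child": conv(node.child)}
        return {
            "op": type(node).__name__.lower(),
            "left": conv(node.left),
            "right": conv(node.right),
        }

    return json.dumps(conv(f), indent=2)
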