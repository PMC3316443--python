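"""Boolean expression trees for rule bodies (equation dialect right-hand sides).

Operators: ``~`` (not), ``&`` (and), ``|`` (or), parentheses; precedence
``~`` > ``&`` > ``|``. Atoms are gene names. Constants have no surface
syntax of their own (a constant rule is written e.g. ``A := A;``) but exist
as tree nodes so that perturbations can clamp a gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = ["Expr", "Const", "Ref", "NotE", "AndE", "OrE"]


class Expr:
    """Base class for rule-body expression nodes."""

    def eval(self, env: Mapping[str, int]) -> int:
        raise NotImplementedError

    def refs(self) -> frozenset[str]:
        raise NotImplementedError

    def to_text(self) -> str:
        return self._fmt(0)

    def _fmt(self, prec: int) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Const(Expr):
    value: int  # 0 or 1

    def eval(self, env):
        return self.value

    def refs(self):
        return frozenset()

    def _fmt(self, prec):
        return "1" if self.value else "0"


@dataclass(frozen=True)
class Ref(Expr):
    name: str

    def eval(self, env):
        return env[self.name]

    def refs(self):
        return frozenset((self.name,))

    def _fmt(self, prec):
        return self.name


@dataclass(frozen=True)
class NotE(Expr):
    child: Expr

    def eval(self, env):
        return 1 - self.child.eval(env)

    def refs(self):
        return self.child.refs()

    def _fmt(self, prec):
        return "~" + self.child._fmt(3)


@dataclass(frozen=True)
class AndE(Expr):
    left: Expr
    right: Expr

    def eval(self, env):
        return self.left.eval(env) & self.right.eval(env)

    def refs(self):
        return self.left.refs() | self.right.refs()

    def _fmt(self, prec):
        s = f"{self.left._fmt(2)} & {self.right._fmt(3)}"
        return f"({s})" if prec > 2 else s


@dataclass(frozen=True)
class OrE(Expr):
    left: Expr
    right: Expr

    def eval(self, env):
        return self.left.eval(env) | self.right.eval(env)

    def refs(self):
        return self.left.refs() | self.right.refs()

    def _fmt(self, prec):
        s = f"{self.left._fmt(1)} | {self.right._fmt(2)}"
        return f"({s})" if prec > 1 else s
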