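"""Brute-force reference semantics, used only to validate the main engine.

Everything here is computed on the enumerated state digraph with plain
Python sets: successor lists come from evaluating every rule at every
state, every operator (including the universal ones) is implemented
directly from its path semantics rather than via the checker's rewriting,
and the binder is literal per-state substitution with no pattern
optimizations. SCC work is delegated to networkx, independent of the
package's own SCC scan. Any disagreement with :mod:`grnmc.checker` on a
test model indicts the main engine, not this module.

Capped at 12 genes; clarity over speed throughout.
"""

from __future__ import annotations

from itertools import product

import networkx as nx

from . import logic as L
from .errors import StateLiteralRangeError, UnboundNameError
from .network import GRN
from .statespace import decode, encode, normalize_mode

__all__ = ["successor_lists", "oracle_eval", "cycle_states_scc"]

_MAX_GENES = 12


def successor_lists(grn: GRN, mode: str) -> list[set[int]]:
    """Successor sets of every state, derived straight from the rules."""
    if grn.n > _MAX_GENES:
        raise ValueError(f"oracle is limited to {_MAX_GENES} genes")
    mode = normalize_mode(mode)
    n = grn.n
    succs: list[set[int]] = []
    for s in range(1 << n):
        values = decode(s, n)
        env = grn.env_of(values)
        allowed = [sorted(grn.rules[g.name].allowed(env)) for g in grn.genes]
        out: set[int] = set()
        if mode == "synchronous":
            for combo in product(*allowed):
                out.add(encode(combo))
        else:
            for i in range(n):
                if (1 - values[i]) in allowed[i]:
                    out.add(s ^ (1 << (n - 1 - i)))
            if all(values[i] in allowed[i] for i in range(n)):
                out.add(s)
        succs.append(out)
    return succs


class _Oracle:
    def __init__(self, grn: GRN, mode: str):
        self.grn = grn
        self.succs = successor_lists(grn, mode)
        self.num_states = 1 << grn.n
        self.all_states = frozenset(range(self.num_states))

    def gene_states(self, name: str) -> frozenset[int]:
        bit = 1 << (self.grn.n - 1 - self.grn.index_of(name))
        return frozenset(s for s in self.all_states if s & bit)

    def eval(self, f: L.Formula, env: dict[str, int]) -> frozenset[int]:
        succs = self.succs
        if isinstance(f, L.TrueF):
            return self.all_states
        if isinstance(f, L.FalseF):
            return frozenset()
        if isinstance(f, L.Name):
            if f.name in env:
                return frozenset((env[f.name],))
            if f.name in self.grn.rules:
                return self.gene_states(f.name)
            raise UnboundNameError(f"unbound name {f.name!r}")
        if isinstance(f, L.StateLit):
            if not (0 <= f.index < self.num_states):
                raise StateLiteralRangeError(f"state literal #{f.index} out of range")
            return frozenset((f.index,))
        if isinstance(f, L.Not):
            return self.all_states - self.eval(f.child, env)
        if isinstance(f, L.And):
            return self.eval(f.left, env) & self.eval(f.right, env)
        if isinstance(f, L.Or):
            return self.eval(f.left, env) | self.eval(f.right, env)
        if isinstance(f, L.Implies):
            return (self.all_states - self.eval(f.left, env)) | self.eval(
                f.right, env
            )
        if isinstance(f, L.EX):
            x = self.eval(f.child, env)
            return frozenset(s for s in self.all_states if succs[s] & x)
        if isinstance(f, L.AX):
            x = self.eval(f.child, env)
            return frozenset(s for s in self.all_states if succs[s] <= x)
        if isinstance(f, L.EY):
            x = self.eval(f.child, env)
            out: set[int] = set()
            for s in x:
                out |= succs[s]
            return frozenset(out)
        if isinstance(f, L.EF):
            return self._lfp(lambda z: self._ex(z), self.eval(f.child, env))
        if isinstance(f, L.AF):
            return self._lfp(lambda z: self._ax(z), self.eval(f.child, env))
        if isinstance(f, L.EG):
            return self._gfp(self._ex, self.eval(f.child, env))
        if isinstance(f, L.AG):
            return self._gfp(self._ax, self.eval(f.child, env))
        if isinstance(f, L.EU):
            hold = self.eval(f.left, env)
            return self._lfp(lambda z: hold & self._ex(z), self.eval(f.right, env))
        if isinstance(f, L.AU):
            hold = self.eval(f.left, env)
            return self._lfp(lambda z: hold & self._ax(z), self.eval(f.right, env))
        if isinstance(f, L.Bind):
            members = set()
            for s in range(self.num_states):
                inner = dict(env)
                inner[f.var] = s
                if s in self.eval(f.body, inner):
                    members.add(s)
            return frozenset(members)
        raise TypeError(f"unknown formula node {f!r}")

    def _ex(self, x: frozenset[int]) -> frozenset[int]:
        return frozenset(s for s in self.all_states if self.succs[s] & x)

    def _ax(self, x: frozenset[int]) -> frozenset[int]:
        return frozenset(s for s in self.all_states if self.succs[s] <= x)

    @staticmethod
    def _lfp(step, seed: frozenset[int]) -> frozenset[int]:
        z = seed
        while True:
            nz = z | seed | step(z)
            if nz == z:
                return z
            z = nz

    @staticmethod
    def _gfp(step, seed: frozenset[int]) -> frozenset[int]:
        z = seed
        while True:
            nz = seed & step(z)
            if nz == z:
                return z
            z = nz


def oracle_eval(
    formula: L.Formula | str,
    grn: GRN,
    mode: str,
    env: dict[str, int] | None = None,
) -> frozenset[int]:
    """State indices satisfying ``formula``, by direct enumeration."""
    if isinstance(formula, str):
        formula = L.parse_formula(formula)
    return _Oracle(grn, mode).eval(formula, dict(env or {}))


def cycle_states_scc(grn: GRN, mode: str) -> frozenset[int]:
    """States on a cycle (non-trivial SCC membership or a self-loop),
    via networkx; the independent check of ``down s . EX EF s``."""
    succs = successor_lists(grn, mode)
    graph = nx.DiGraph()
    graph.add_nodes_from(range(len(succs)))
    for s, outs in enumerate(succs):
        graph.add_edges_from((s, t) for t in outs)
    out: set[int] = set()
    for comp in nx.strongly_connected_components(graph):
        if len(comp) > 1:
            out |= comp
    out.update(s for s, outs in enumerate(succs) if s in outs)
    return frozenset(out)
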