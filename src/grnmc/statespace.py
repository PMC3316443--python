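"""State spaces and transition relations of Boolean GRNs.

A network of ``n`` genes induces ``2^n`` states. A state is numbered by
reading its gene values as a binary word whose most significant bit is the
lexicographically first gene, so profiles and indices convert both ways
(:func:`encode` / :func:`decode`).

:func:`build_transitions` constructs the total transition relation under
either update mode:

* **synchronous** — ``s -> s'`` iff for every gene ``g``, ``s'(g)`` is an
  allowed next value of ``g`` at ``s`` (indeterminations multiply out as a
  Cartesian product of choices);
* **asynchronous** — one gene changes per transition: for every gene ``g``
  and allowed value ``v != s(g)`` there is an edge ``s -> s[g:=v]``, and
  ``s`` carries a self-loop iff *every* gene may keep its current value.
  Fixed points therefore self-loop, states whose only indeterminate rule
  rows allow holding get a self-loop plus exits (unstable steady states),
  and deterministic transients get no spurious self-loop.

Two interchangeable backends implement one state-set contract: an explicit
enumeration backend (adjacency sets; the reference for small ``n``) and a
symbolic backend holding both sets and the relation as BDDs over ``2n``
interleaved bits (gene ``i`` owns levels ``2i`` for its current value and
``2i + 1`` for its next value).
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Iterator, Sequence

from .bdd import BDD
from .network import GRN

__all__ = [
    "encode",
    "decode",
    "StateSet",
    "build_transitions",
    "ExplicitRelation",
    "SymbolicRelation",
    "successors",
    "preimage",
    "postimage",
    "out_degree_at_least",
    "normalize_mode",
    "edges_tsv",
    "strongly_connected_components",
    "cycle_state_indices",
]


def normalize_mode(mode: str) -> str:
    m = mode.lower()
    if m in ("sync", "synchronous"):
        return "synchronous"
    if m in ("async", "asynchronous"):
        return "asynchronous"
    raise ValueError(f"unknown update mode {mode!r}")


def encode(values: Sequence[int]) -> int:
    """State index of a gene-value vector (canonical gene order, first gene
    most significant)."""
    index = 0
    for v in values:
        index = (index << 1) | (1 if v else 0)
    return index


def decode(index: int, n: int) -> tuple[int, ...]:
    return tuple((index >> (n - 1 - i)) & 1 for i in range(n))


class StateSet:
    """A set of states, closed under Boolean algebra; backend-opaque payload
    (a frozenset of indices or a BDD node)."""

    __slots__ = ("rel", "payload")

    def __init__(self, rel: "_Relation", payload):
        self.rel = rel
        self.payload = payload

    def _check(self, other: "StateSet") -> None:
        if self.rel is not other.rel:
            raise ValueError("state sets belong to different models/backends")

    def __or__(self, other: "StateSet") -> "StateSet":
        self._check(other)
        return StateSet(self.rel, self.rel._union(self.payload, other.payload))

    def __and__(self, other: "StateSet") -> "StateSet":
        self._check(other)
        return StateSet(self.rel, self.rel._intersect(self.payload, other.payload))

    def __sub__(self, other: "StateSet") -> "StateSet":
        self._check(other)
        return StateSet(self.rel, self.rel._difference(self.payload, other.payload))

    def __invert__(self) -> "StateSet":
        return StateSet(self.rel, self.rel._complement(self.payload))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StateSet)
            and self.rel is other.rel
            and self.payload == other.payload
        )

    def __hash__(self):
        return hash(self.payload)

    def __len__(self) -> int:
        return self.rel._size(self.payload)

    def __contains__(self, index: int) -> bool:
        return self.rel._contains(self.payload, index)

    def __bool__(self) -> bool:
        return not self.rel._is_empty(self.payload)

    def issubset(self, other: "StateSet") -> bool:
        self._check(other)
        return self.rel._is_empty(
            self.rel._difference(self.payload, other.payload)
        )

    def indices(self) -> tuple[int, ...]:
        return self.rel._indices(self.payload)

    def __repr__(self):
        n = len(self)
        shown = ", ".join(map(str, self.indices()[:8]))
        more = ", ..." if n > 8 else ""
        return f"StateSet({{{shown}{more}}}, size={n})"


class _Relation:
    """Shared behavior of both transition-relation backends."""

    grn: GRN
    mode: str

    def __init__(self, grn: GRN, mode: str):
        self.grn = grn
        self.mode = normalize_mode(mode)
        self.n = grn.n
        self.num_states = 1 << grn.n
        self.last_scan: dict[str, int] = {}

    # set constructors -----------------------------------------------------
    def empty(self) -> StateSet:
        return self.from_indices(())

    def full(self) -> StateSet:
        raise NotImplementedError

    def singleton(self, index: int) -> StateSet:
        return self.from_indices((index,))

    def from_indices(self, indices: Iterable[int]) -> StateSet:
        raise NotImplementedError

    def gene_true(self, gene: str) -> StateSet:
        """States in which ``gene`` is active."""
        raise NotImplementedError

    # relation queries ------------------------------------------------------
    def preimage(self, X: StateSet) -> StateSet:
        raise NotImplementedError

    def postimage(self, X: StateSet) -> StateSet:
        raise NotImplementedError

    def successors(self, index: int) -> StateSet:
        return self.postimage(self.singleton(index))

    def self_loop_states(self) -> StateSet:
        raise NotImplementedError

    def two_cycle_states(self) -> StateSet:
        """States with a distinct partner ``t`` such that ``s -> t -> s``."""
        raise NotImplementedError

    def edges(self) -> Iterator[tuple[int, int]]:
        raise NotImplementedError

    @property
    def num_transitions(self) -> int:
        raise NotImplementedError

    def out_degree_at_least(self, k: int) -> StateSet:
        """States with at least ``k`` successors (``k`` in {1, 2}), by a
        single pass over the relation; ``last_scan`` records the work done."""
        if k not in (1, 2):
            raise ValueError("k must be 1 or 2")
        counts: dict[int, int] = {}
        states_touched = 0
        edges_touched = 0
        for s, _t in self.edges():
            counts[s] = counts.get(s, 0) + 1
            edges_touched += 1
        states_touched = self.num_states
        self.last_scan = {"states": states_touched, "edges": edges_touched}
        return self.from_indices(s for s, c in counts.items() if c >= k)


# ---------------------------------------------------------------------------


def _allowed_profile(grn: GRN, values: tuple[int, ...]) -> list[frozenset[int]]:
    env = grn.env_of(values)
    return [grn.rules[g.name].allowed(env) for g in grn.genes]


class ExplicitRelation(_Relation):
    """Adjacency-set backend; the oracle-grade reference for small ``n``."""

    def __init__(self, grn: GRN, mode: str):
        super().__init__(grn, mode)
        if grn.n > 20:
            raise ValueError("explicit backend is limited to 20 genes")
        n = self.n
        succs: list[frozenset[int]] = []
        preds: list[set[int]] = [set() for _ in range(self.num_states)]
        sync = self.mode == "synchronous"
        for s in range(self.num_states):
            values = decode(s, n)
            allowed = _allowed_profile(grn, values)
            out: set[int] = set()
            if sync:
                for combo in product(*allowed):
                    out.add(encode(combo))
            else:
                for i in range(n):
                    v = 1 - values[i]
                    if v in allowed[i]:
                        out.add(s ^ (1 << (n - 1 - i)))
                if all(values[i] in allowed[i] for i in range(n)):
                    out.add(s)
            succs.append(frozenset(out))
            for t in out:
                preds[t].add(s)
        self.succs = succs
        self.preds = [frozenset(p) for p in preds]

    # set algebra ---------------------------------------------------------
    def full(self) -> StateSet:
        return StateSet(self, frozenset(range(self.num_states)))

    def from_indices(self, indices: Iterable[int]) -> StateSet:
        return StateSet(self, frozenset(indices))

    def gene_true(self, gene: str) -> StateSet:
        bit = 1 << (self.n - 1 - self.grn.index_of(gene))
        return StateSet(self, frozenset(s for s in range(self.num_states) if s & bit))

    def _union(self, a, b):
        return a | b

    def _intersect(self, a, b):
        return a & b

    def _difference(self, a, b):
        return a - b

    def _complement(self, a):
        return frozenset(range(self.num_states)) - a

    def _size(self, a):
        return len(a)

    def _contains(self, a, index):
        return index in a

    def _is_empty(self, a):
        return not a

    def _indices(self, a):
        return tuple(sorted(a))

    # relation queries ------------------------------------------------------
    def preimage(self, X: StateSet) -> StateSet:
        out: set[int] = set()
        for t in X.payload:
            out |= self.preds[t]
        return StateSet(self, frozenset(out))

    def postimage(self, X: StateSet) -> StateSet:
        out: set[int] = set()
        for s in X.payload:
            out |= self.succs[s]
        return StateSet(self, frozenset(out))

    def self_loop_states(self) -> StateSet:
        return StateSet(
            self, frozenset(s for s in range(self.num_states) if s in self.succs[s])
        )

    def two_cycle_states(self) -> StateSet:
        out = set()
        for s in range(self.num_states):
            for t in self.succs[s]:
                if t != s and s in self.succs[t]:
                    out.add(s)
                    break
        return StateSet(self, frozenset(out))

    def edges(self) -> Iterator[tuple[int, int]]:
        for s in range(self.num_states):
            for t in self.succs[s]:
                yield s, t

    @property
    def num_transitions(self) -> int:
        return sum(len(x) for x in self.succs)


# ---------------------------------------------------------------------------


class SymbolicRelation(_Relation):
    """BDD backend (default): sets over current-value levels, the relation
    over current and next levels interleaved."""

    def __init__(self, grn: GRN, mode: str):
        super().__init__(grn, mode)
        b = self.bdd = BDD()
        n = self.n
        self._cur = [2 * i for i in range(n)]
        self._nxt = [2 * i + 1 for i in range(n)]
        cur_var = [b.var(l) for l in self._cur]
        nxt_var = [b.var(l) for l in self._nxt]

        # per-gene sets of states whose rule allows next value 1 (resp. 0)
        can1: list[int] = []
        can0: list[int] = []
        for g in grn.genes:
            rule = grn.rules[g.name]
            if rule.is_table:
                k = len(rule.regulators)
                ones = []
                zeros = []
                for row, out in enumerate(rule.outputs):
                    cube = b.cube(
                        {
                            2 * grn.index_of(reg): (row >> (k - 1 - j)) & 1
                            for j, reg in enumerate(rule.regulators)
                        }
                    )
                    if out in "1*":
                        ones.append(cube)
                    if out in "0*":
                        zeros.append(cube)
                can1.append(b.all_or(ones))
                can0.append(b.all_or(zeros))
            else:
                bodies = [self._expr_bdd(body) for body in rule.bodies]
                can1.append(b.all_or(bodies))
                can0.append(b.all_or(b.NOT(e) for e in bodies))

        hold = [
            b.OR(b.AND(cur_var[i], can1[i]), b.AND(b.NOT(cur_var[i]), can0[i]))
            for i in range(n)
        ]
        same = [b.IFF(cur_var[i], nxt_var[i]) for i in range(n)]
        self._diag = b.all_and(same)

        if self.mode == "synchronous":
            self.relation = b.all_and(
                b.OR(b.AND(nxt_var[i], can1[i]), b.AND(b.NOT(nxt_var[i]), can0[i]))
                for i in range(n)
            )
        else:
            parts = [b.AND(b.all_and(hold), self._diag)]
            for i in range(n):
                flip = b.OR(
                    b.all_and([nxt_var[i], b.NOT(cur_var[i]), can1[i]]),
                    b.all_and([b.NOT(nxt_var[i]), cur_var[i], can0[i]]),
                )
                frame = b.all_and(same[j] for j in range(n) if j != i)
                parts.append(b.AND(flip, frame))
            self.relation = b.all_or(parts)

    def _expr_bdd(self, expr) -> int:
        from ._expr import AndE, Const, NotE, OrE, Ref

        b = self.bdd
        if isinstance(expr, Const):
            return 1 if expr.value else 0
        if isinstance(expr, Ref):
            return b.var(2 * self.grn.index_of(expr.name))
        if isinstance(expr, NotE):
            return b.NOT(self._expr_bdd(expr.child))
        if isinstance(expr, AndE):
            return b.AND(self._expr_bdd(expr.left), self._expr_bdd(expr.right))
        if isinstance(expr, OrE):
            return b.OR(self._expr_bdd(expr.left), self._expr_bdd(expr.right))
        raise TypeError(f"unknown expression node {expr!r}")

    # set algebra ---------------------------------------------------------
    def full(self) -> StateSet:
        return StateSet(self, 1)

    def from_indices(self, indices: Iterable[int]) -> StateSet:
        b = self.bdd
        n = self.n
        return StateSet(
            self,
            b.all_or(
                b.cube({2 * i: (s >> (n - 1 - i)) & 1 for i in range(n)})
                for s in indices
            ),
        )

    def gene_true(self, gene: str) -> StateSet:
        return StateSet(self, self.bdd.var(2 * self.grn.index_of(gene)))

    def _union(self, a, b):
        return self.bdd.OR(a, b)

    def _intersect(self, a, b):
        return self.bdd.AND(a, b)

    def _difference(self, a, b):
        return self.bdd.DIFF(a, b)

    def _complement(self, a):
        return self.bdd.NOT(a)

    def _size(self, a):
        return self.bdd.satcount(a, self._cur)

    def _contains(self, a, index):
        n = self.n
        cube = self.bdd.cube({2 * i: (index >> (n - 1 - i)) & 1 for i in range(n)})
        return self.bdd.AND(a, cube) != 0

    def _is_empty(self, a):
        return a == 0

    def _indices(self, a):
        return tuple(
            encode(bits) for bits in self.bdd.iter_sat(a, self._cur)
        )

    # relation queries ------------------------------------------------------
    def _to_next(self, a: int) -> int:
        return self.bdd.rename({2 * i: 2 * i + 1 for i in range(self.n)}, a)

    def _to_cur(self, a: int) -> int:
        return self.bdd.rename({2 * i + 1: 2 * i for i in range(self.n)}, a)

    def preimage(self, X: StateSet) -> StateSet:
        b = self.bdd
        primed = self._to_next(X.payload)
        return StateSet(self, b.exists(self._nxt, b.AND(self.relation, primed)))

    def postimage(self, X: StateSet) -> StateSet:
        b = self.bdd
        img = b.exists(self._cur, b.AND(self.relation, X.payload))
        return StateSet(self, self._to_cur(img))

    def self_loop_states(self) -> StateSet:
        b = self.bdd
        return StateSet(
            self, b.exists(self._nxt, b.AND(self.relation, self._diag))
        )

    def two_cycle_states(self) -> StateSet:
        b = self.bdd
        swap: dict[int, int] = {}
        for i in range(self.n):
            swap[2 * i] = 2 * i + 1
            swap[2 * i + 1] = 2 * i
        reverse = b.rename(swap, self.relation)
        mutual = b.AND(self.relation, b.AND(reverse, b.NOT(self._diag)))
        return StateSet(self, b.exists(self._nxt, mutual))

    def edges(self) -> Iterator[tuple[int, int]]:
        n = self.n
        for bits in self.bdd.iter_sat(self.relation, range(2 * n)):
            s = encode(bits[0::2])
            t = encode(bits[1::2])
            yield s, t

    @property
    def num_transitions(self) -> int:
        return self.bdd.satcount(self.relation, range(2 * self.n))


# ---------------------------------------------------------------------------
# module-level operation wrappers


def build_transitions(grn: GRN, mode: str, backend: str = "symbolic") -> _Relation:
    """Build the total transition relation of ``grn`` under ``mode`` using
    the requested backend (``symbolic`` | ``explicit``)."""
    if backend == "symbolic":
        return SymbolicRelation(grn, mode)
    if backend == "explicit":
        return ExplicitRelation(grn, mode)
    raise ValueError(f"unknown backend {backend!r}")


def successors(rel: _Relation, index: int) -> StateSet:
    return rel.successors(index)


def preimage(rel: _Relation, X: StateSet) -> StateSet:
    return rel.preimage(X)


def postimage(rel: _Relation, X: StateSet) -> StateSet:
    return rel.postimage(X)


def out_degree_at_least(rel: _Relation, k: int) -> StateSet:
    return rel.out_degree_at_least(k)


def edges_tsv(rel: _Relation) -> str:
    """Edge list export: one ``source_index<TAB>target_index`` line per
    transition, sorted."""
    lines = ["source_index\ttarget_index"]
    for s, t in sorted(rel.edges()):
        lines.append(f"{s}\t{t}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# graph algorithms on the relation (used by the optimizer and by recipes;
# the test oracle uses networkx independently)


def strongly_connected_components(rel: _Relation) -> list[list[int]]:
    """SCCs of the state-transition graph (iterative Kosaraju), restricted
    to states reachable in the adjacency built from the relation's edges."""
    succs: dict[int, list[int]] = {}
    preds: dict[int, list[int]] = {}
    for s, t in rel.edges():
        succs.setdefault(s, []).append(t)
        preds.setdefault(t, []).append(s)

    visited: set[int] = set()
    order: list[int] = []
    for root in range(rel.num_states):
        if root in visited:
            continue
        stack: list[tuple[int, int]] = [(root, 0)]
        visited.add(root)
        while stack:
            node, i = stack.pop()
            nexts = succs.get(node, ())
            if i < len(nexts):
                stack.append((node, i + 1))
                child = nexts[i]
                if child not in visited:
                    visited.add(child)
                    stack.append((child, 0))
            else:
                order.append(node)

    assigned: set[int] = set()
    components: list[list[int]] = []
    for root in reversed(order):
        if root in assigned:
            continue
        comp = [root]
        assigned.add(root)
        stack2 = [root]
        while stack2:
            node = stack2.pop()
            for p in preds.get(node, ()):
                if p not in assigned:
                    assigned.add(p)
                    comp.append(p)
                    stack2.append(p)
        components.append(comp)
    return components


def cycle_state_indices(rel: _Relation) -> set[int]:
    """States lying on some cycle: members of a non-trivial SCC, plus
    self-loop states."""
    out: set[int] = set()
    for comp in strongly_connected_components(rel):
        if len(comp) > 1:
            out.update(comp)
    for s in rel.self_loop_states().indices():
        out.add(s)
    return out
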