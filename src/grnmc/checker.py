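"""Set-returning model checking: the labeling algorithm plus hybrid binders.

Evaluation is bottom-up over the rewritten formula (derived operators
eliminated first): gene atoms and literals come straight from the state
numbering, Boolean connectives are set algebra, ``EX`` is one reverse
traversal (preimage), ``EY`` one forward traversal (postimage), and
``EF``/``EG``/``EU`` are the usual least/greatest fixpoints iterated with
frontiers. A ``down``-binder re-runs the labeling algorithm once per state
of the model — except when the formula matches one of five special-cased
patterns, which are answered by direct relation inspection instead:

========================================  =====================================
pattern (up to bound-variable renaming)   answered by
========================================  =====================================
``down s . EX s``                         self-loop states
``down s . AX s``                         self-loops with out-degree exactly 1
                                          (the stable steady states)
``down s . EX EF s``                      states on a cycle (SCC scan)
``down s . EX ((not s) and EX s)``        states in a two-cycle with a
                                          distinct partner
``down s . EX down t . EY (s and EX not t)``  states with >= 2 successors,
                                          one pass over states + transitions
========================================  =====================================

Pattern matching is purely syntactic (after rewriting), so a formula that
is merely semantically equivalent to a pattern takes the naive per-state
plan — predictable over clever. Subformula results are memoized keyed on
(subformula, bindings restricted to its free names), which keeps nested
binders tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import logic as L
from .errors import StateLiteralRangeError, UnboundNameError
from .network import GRN
from .statespace import (
    StateSet,
    _Relation,
    build_transitions,
    cycle_state_indices,
)

__all__ = [
    "Model",
    "evaluate",
    "optimize",
    "steady_state_report",
    "PLAN_SELF_LOOP",
    "PLAN_STABLE",
    "PLAN_CYCLE",
    "PLAN_TWO_CYCLE",
    "PLAN_MULTI_SUCCESSOR",
    "PLAN_NAIVE",
]

logger = logging.getLogger("grnmc.checker")

PLAN_SELF_LOOP = "self-loop"
PLAN_STABLE = "stable-self-loop"
PLAN_CYCLE = "cycle-scc"
PLAN_TWO_CYCLE = "two-cycle"
PLAN_MULTI_SUCCESSOR = "multi-successor"
PLAN_NAIVE = "naive"

# patterns are stated in rewritten form (AX already expanded)
_P_SELF = L.Bind("s", L.EX(L.Name("s")))
_P_STABLE = L.Bind("s", L.Not(L.EX(L.Not(L.Name("s")))))
_P_CYCLE = L.Bind("s", L.EX(L.EF(L.Name("s"))))
_P_TWO_CYCLE = L.Bind("s", L.EX(L.And(L.Not(L.Name("s")), L.EX(L.Name("s")))))
_P_MULTI = L.Bind(
    "s",
    L.EX(
        L.Bind(
            "t",
            L.EY(L.And(L.Name("s"), L.EX(L.Not(L.Name("t"))))),
        )
    ),
)

_PATTERNS = (
    (_P_SELF, PLAN_SELF_LOOP),
    (_P_STABLE, PLAN_STABLE),
    (_P_CYCLE, PLAN_CYCLE),
    (_P_TWO_CYCLE, PLAN_TWO_CYCLE),
    (_P_MULTI, PLAN_MULTI_SUCCESSOR),
)


@dataclass
class Model:
    """A network together with its Kripke structure under one update mode."""

    grn: GRN
    mode: str = "asynchronous"
    backend: str = "symbolic"
    rel: _Relation = field(init=False, repr=False)

    def __post_init__(self):
        self.rel = build_transitions(self.grn, self.mode, self.backend)
        self.mode = self.rel.mode

    def evaluate(self, formula, env=None, use_optimizations: bool = True) -> StateSet:
        return evaluate(self, formula, env, use_optimizations)


def _match(f: L.Formula, pattern: L.Formula) -> bool:
    """Alpha-insensitive syntactic match against a closed pattern whose only
    names are its own bound variables."""
    return L.alpha_equal(f, pattern)


def optimize(f: L.Formula) -> str:
    """The evaluation plan the checker will use for a binder formula (one of
    the ``PLAN_*`` constants); called on the rewritten formula or any
    formula (it rewrites internally)."""
    f = L.rewrite_derived(f)
    for pattern, plan in _PATTERNS:
        if _match(f, pattern):
            return plan
    return PLAN_NAIVE


class _Evaluator:
    def __init__(self, model: Model, use_optimizations: bool):
        self.model = model
        self.rel = model.rel
        self.opt = use_optimizations
        self.memo: dict = {}
        self.genes = set(model.grn.names)

    def _env_key(self, f: L.Formula, env: dict[str, int]):
        names = L._free_names(f)
        return tuple(sorted((v, env[v]) for v in names if v in env))

    def eval(self, f: L.Formula, env: dict[str, int]) -> StateSet:
        key = (f, self._env_key(f, env))
        hit = self.memo.get(key)
        if hit is not None:
            return hit
        out = self._eval(f, env)
        self.memo[key] = out
        return out

    def _eval(self, f: L.Formula, env: dict[str, int]) -> StateSet:
        rel = self.rel
        if isinstance(f, L.TrueF):
            return rel.full()
        if isinstance(f, L.FalseF):
            return rel.empty()
        if isinstance(f, L.Name):
            if f.name in env:
                return rel.singleton(env[f.name])
            if f.name in self.genes:
                return rel.gene_true(f.name)
            raise UnboundNameError(
                f"{f.name!r} is neither a gene of this model nor a bound state variable"
            )
        if isinstance(f, L.StateLit):
            if not (0 <= f.index < rel.num_states):
                raise StateLiteralRangeError(
                    f"state literal #{f.index} out of range for a "
                    f"{rel.n}-gene model ({rel.num_states} states)"
                )
            return rel.singleton(f.index)
        if isinstance(f, L.Not):
            return ~self.eval(f.child, env)
        if isinstance(f, L.And):
            return self.eval(f.left, env) & self.eval(f.right, env)
        if isinstance(f, L.Or):
            return self.eval(f.left, env) | self.eval(f.right, env)
        if isinstance(f, L.EX):
            return rel.preimage(self.eval(f.child, env))
        if isinstance(f, L.EY):
            return rel.postimage(self.eval(f.child, env))
        if isinstance(f, L.EF):
            return self._lfp_reach(self.eval(f.child, env))
        if isinstance(f, L.EG):
            return self._gfp_invariant(self.eval(f.child, env))
        if isinstance(f, L.EU):
            return self._lfp_until(self.eval(f.left, env), self.eval(f.right, env))
        if isinstance(f, L.Bind):
            return self._bind(f, env)
        raise TypeError(f"unexpected formula node after rewriting: {f!r}")

    # fixpoints ----------------------------------------------------------
    def _lfp_reach(self, target: StateSet) -> StateSet:
        z = target
        frontier = target
        iterations = 0
        while frontier:
            new = self.rel.preimage(frontier) - z
            z = z | new
            frontier = new
            iterations += 1
        logger.debug("EF fixpoint converged in %d iterations", iterations)
        return z

    def _lfp_until(self, hold: StateSet, target: StateSet) -> StateSet:
        z = target
        frontier = target
        iterations = 0
        while frontier:
            new = (hold & self.rel.preimage(frontier)) - z
            z = z | new
            frontier = new
            iterations += 1
        logger.debug("EU fixpoint converged in %d iterations", iterations)
        return z

    def _gfp_invariant(self, inv: StateSet) -> StateSet:
        z = inv
        iterations = 0
        while True:
            nxt = inv & self.rel.preimage(z)
            iterations += 1
            if nxt == z:
                break
            z = nxt
        logger.debug("EG fixpoint converged in %d iterations", iterations)
        return z

    # hybrid binder -------------------------------------------------------
    def _bind(self, f: L.Bind, env: dict[str, int]) -> StateSet:
        rel = self.rel
        if self.opt:
            for pattern, plan in _PATTERNS:
                if _match(f, pattern):
                    logger.debug("binder plan: %s", plan)
                    return self._run_plan(plan)
        logger.debug("binder plan: %s (per-state labeling)", PLAN_NAIVE)
        members = []
        for s in range(rel.num_states):
            inner = dict(env)
            inner[f.var] = s
            if s in self.eval(f.body, inner):
                members.append(s)
        return rel.from_indices(members)

    def _run_plan(self, plan: str) -> StateSet:
        rel = self.rel
        if plan == PLAN_SELF_LOOP:
            return rel.self_loop_states()
        if plan == PLAN_STABLE:
            return rel.self_loop_states() - rel.out_degree_at_least(2)
        if plan == PLAN_CYCLE:
            return rel.from_indices(cycle_state_indices(rel))
        if plan == PLAN_TWO_CYCLE:
            return rel.two_cycle_states()
        if plan == PLAN_MULTI_SUCCESSOR:
            return rel.out_degree_at_least(2)
        raise AssertionError(plan)


def evaluate(
    model: Model,
    formula: L.Formula | str,
    env: dict[str, int] | None = None,
    use_optimizations: bool = True,
) -> StateSet:
    """Set of states of ``model`` satisfying ``formula``.

    ``env`` provides bindings for any free state variables (name -> state
    index). Raises :class:`UnboundNameError` for names that are neither
    genes nor bound, and :class:`StateLiteralRangeError` for oversized
    ``#k`` literals.
    """
    if isinstance(formula, str):
        formula = L.parse_formula(formula)
    env = dict(env or {})
    free = L.free_vars(formula, set(model.grn.names)) - set(env)
    if free:
        raise UnboundNameError(
            "free state variables without a binding: " + ", ".join(sorted(free))
        )
    f = L.rewrite_derived(formula)
    logger.debug(
        "evaluate: backend=%s mode=%s formula=%s",
        model.backend,
        model.mode,
        L.pretty(formula),
    )
    return _Evaluator(model, use_optimizations).eval(f, env)


def steady_state_report(model: Model) -> tuple[StateSet, StateSet]:
    """(stable, unstable) steady states: states whose only transition is
    their self-loop, and states with a self-loop plus exits."""
    stable = evaluate(model, L.parse_formula("down s . AX s"))
    loops = evaluate(model, L.parse_formula("down s . EX s"))
    return stable, loops - stable
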