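"""Canned biological queries over a model.

Each recipe is a thin, named layer over the checker: steady states,
attractor membership in the cycle sense (states lying on *some* cycle of
the state-transition graph — the hybrid-formula notion, which also picks
up non-terminal cycles), basins of attraction, conditional reachability,
and perturbation screens. :func:`terminal_attractors` is the different,
SCC-based notion (terminal strongly connected components, i.e. where
trajectories end up); the two deliberately carry different names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from . import checker as C
from .statespace import StateSet, decode, strongly_connected_components

__all__ = [
    "QueryResult",
    "query_result",
    "attractor_states",
    "two_cycle_states",
    "multi_successor_states",
    "basin",
    "small_attractor_basin_complement",
    "reach_avoiding",
    "reach_through",
    "mutant_screen",
    "terminal_attractors",
    "model_fingerprint",
    "RECIPE_FORMULAS",
]

RECIPE_FORMULAS = {
    "stable-steady-states": "down s . AX s",
    "steady-states": "down s . EX s",
    "attractors": "down s . EX EF s",
    "two-cycles": "down s . EX ((not s) and EX s)",
    "multi-successor": "down s . EX down t . EY (s and EX not t)",
    "small-attractor-basin-complement": "not EF (down s . EX EX s)",
}


def model_fingerprint(model: C.Model) -> str:
    payload = model.grn.to_json() + "\n" + model.mode
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class QueryResult:
    """A named state set with provenance, ready for JSON/TSV export."""

    query: str
    formula: str
    mode: str
    count: int
    state_indices: list[int]
    states: list[dict[str, int]]
    model_fingerprint: str
    capped: bool = False

    def to_dict(self) -> dict:
        return {
            "query": self.query,
            "formula": self.formula,
            "mode": self.mode,
            "count": self.count,
            "capped": self.capped,
            "state_indices": self.state_indices,
            "states": self.states,
            "model_fingerprint": self.model_fingerprint,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        if not self.states:
            genes: list[str] = []
        else:
            genes = list(self.states[0])
        lines = ["\t".join(["state_index"] + genes)]
        for idx, row in zip(self.state_indices, self.states):
            lines.append("\t".join([str(idx)] + [str(row[g]) for g in genes]))
        return "\n".join(lines) + "\n"


def query_result(
    model: C.Model,
    name: str,
    sset: StateSet,
    formula: str = "",
    cap: int = 10_000,
) -> QueryResult:
    """Wrap a state set; enumeration is capped at ``cap`` rows but the
    count is always exact."""
    count = len(sset)
    indices = sset.indices()[: cap if cap >= 0 else None]
    names = model.grn.names
    rows = [
        dict(zip(names, decode(i, model.grn.n))) for i in indices
    ]
    return QueryResult(
        query=name,
        formula=formula,
        mode=model.mode,
        count=count,
        state_indices=list(indices),
        states=rows,
        model_fingerprint=model_fingerprint(model),
        capped=count > len(indices),
    )


# -- formula recipes ---------------------------------------------------------


def attractor_states(model: C.Model) -> StateSet:
    """States lying on some cycle (attractors of any size, in the
    hybrid-formula sense)."""
    return C.evaluate(model, RECIPE_FORMULAS["attractors"])


def two_cycle_states(model: C.Model) -> StateSet:
    """States belonging to a size-two attractor."""
    return C.evaluate(model, RECIPE_FORMULAS["two-cycles"])


def multi_successor_states(model: C.Model) -> StateSet:
    """States with more than one immediate successor."""
    return C.evaluate(model, RECIPE_FORMULAS["multi-successor"])


def small_attractor_basin_complement(model: C.Model) -> StateSet:
    """Complement of the basins of one- and two-state attractors."""
    return C.evaluate(model, RECIPE_FORMULAS["small-attractor-basin-complement"])


# -- reachability recipes (targets given as state sets) ----------------------


def basin(model: C.Model, target: StateSet) -> StateSet:
    """Basin of attraction: all states from which ``target`` is reachable
    (reflexively, so the target is inside its own basin)."""
    rel = model.rel
    z = target
    frontier = target
    while frontier:
        new = rel.preimage(frontier) - z
        z = z | new
        frontier = new
    return z


def reach_avoiding(model: C.Model, target: StateSet, avoid: StateSet) -> StateSet:
    """States from which ``target`` is reachable going only through states
    outside ``avoid`` — ``E[(not avoid) U target]``."""
    rel = model.rel
    hold = ~avoid
    z = target
    frontier = target
    while frontier:
        new = (hold & rel.preimage(frontier)) - z
        z = z | new
        frontier = new
    return z


def reach_through(model: C.Model, target: StateSet, via: StateSet) -> StateSet:
    """States that can reach ``target`` but only through ``via`` —
    ``not E[(not via) U target] and EF target``."""
    return basin(model, target) - reach_avoiding(model, target, via)


# -- perturbations -----------------------------------------------------------


def mutant_screen(
    model: C.Model, gene: str, clamp: int, cap: int = 10_000
) -> dict[str, QueryResult]:
    """Steady-state report of the network with ``gene`` clamped to
    ``clamp``, plus the stable set's basin and its one-step backward
    (``EX``) and forward (``EY``) neighborhoods for inspection."""
    mutant = C.Model(
        model.grn.perturb(gene, clamp), mode=model.mode, backend=model.backend
    )
    stable, unstable = C.steady_state_report(mutant)
    out = {
        "stable": query_result(
            mutant, "stable", stable, RECIPE_FORMULAS["stable-steady-states"], cap
        ),
        "unstable": query_result(mutant, "unstable", unstable, "", cap),
        "basin_of_stable": query_result(
            mutant, "basin_of_stable", basin(mutant, stable), "EF stable", cap
        ),
        "ex_of_stable": query_result(
            mutant, "ex_of_stable", mutant.rel.preimage(stable), "EX stable", cap
        ),
        "ey_of_stable": query_result(
            mutant, "ey_of_stable", mutant.rel.postimage(stable), "EY stable", cap
        ),
    }
    return out


# -- terminal attractors (SCC-based, distinct from the formula notion) -------


def terminal_attractors(model: C.Model) -> list[StateSet]:
    """Terminal strongly connected components (where trajectories end up),
    one state set per attractor, sorted by smallest member."""
    rel = model.rel
    comps = strongly_connected_components(rel)
    member: dict[int, int] = {}
    for ci, comp in enumerate(comps):
        for s in comp:
            member[s] = ci
    terminal = [True] * len(comps)
    for s, t in rel.edges():
        if member[s] != member[t]:
            terminal[member[s]] = False
    out = [
        rel.from_indices(comp)
        for ci, comp in enumerate(comps)
        if terminal[ci]
    ]
    return sorted(out, key=lambda x: x.indices()[0])
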