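# Methods

## Model

A Boolean GRN assigns each gene `X` a rule constraining its next value as
a function of the current values of its regulators. Rules may be
*indeterminate*: the allowed next values of `(state, gene)` form a
non-empty subset of `{0, 1}`. In the equation dialect an indetermination
is written as several equations with the same left-hand side (the allowed
set is the union of the bodies' values); in the table dialect as a `*`
output row. Indeterminations model three distinct phenomena on one
mechanism: asynchrony, incompletely specified regulation, and input from
the environment.

Gene order is canonical — ASCII-lexicographic by name — and a state is
numbered by its gene values read as binary with the first gene most
significant. This fixes `#k` literals and all reported indices
reproducibly.

### Transition semantics

Both update modes yield a *total* relation over the `2^n` states:

* **synchronous**: `s → s'` iff every gene's next value in `s'` is
  allowed at `s`; choices multiply out, so the successor count is the
  product of the per-gene allowed-set sizes.
* **asynchronous**: for every gene `g` and allowed `v ≠ s(g)` there is an
  edge `s → s[g:=v]`; `s` self-loops iff **every** gene may keep its
  current value.

The asynchronous self-loop rule is a genuine design choice: the
convention here is the weakest one that makes the steady-state taxonomy
expressible — fixed points self-loop (so `down s . AX s` finds them), a
state whose indeterminate rows allow holding gets a self-loop *plus*
exits (an unstable steady state, `down s . EX s` minus the stable set),
and deterministic transients get no spurious self-loops (so basins and
`EG` read naturally). A per-gene "hold" convention (self-loop whenever
*some* gene may hold) would flood transient states with self-loops and
make `EG φ` nearly vacuous.

## Logic and evaluation

The logic is CTL plus the hybrid binder `down σ . φ`, state variables,
state literals and the past operator `EY`. Derived operators are
eliminated first (`AX = not EX not`, `AG = not EF not`,
`AF = not EG not`, `A[φ U ψ] = not (E[not ψ U (not φ and not ψ)] or
EG not ψ)`, `implies = not/or`); the labeling core then handles atoms and
literals directly, Boolean connectives as set algebra, `EX` as preimage,
`EY` as postimage, and the fixpoints

* `EF φ = lfp Z . φ ∪ pre(Z)` (reflexive: "now or in the future" — the
  present is included in `F` and `G`),
* `EG φ = gfp Z . φ ∩ pre(Z)`,
* `E[φ U ψ] = lfp Z . ψ ∪ (φ ∩ pre(Z))`.

Least fixpoints are frontier-based (only newly added states are expanded
in the next round), which matters for the BDD backend; convergence takes
at most `2^n` rounds and is logged. Subformula results are memoized keyed
on `(subformula, environment restricted to its free names)`; this is what
keeps nested binders tractable, because the σ-independent parts of a
binder body are computed once rather than once per state.

Gene atoms and state variables share one namespace, resolved by binding:
a name evaluates as the innermost enclosing `down` binding if one exists,
else as a gene atom, else it is an error. A binder therefore shadows a
like-named gene — the price of a grammar in which `free_vars` is purely
syntactic. Binders nest to arbitrary depth.

### Binder plans

`down σ . φ` costs one labeling run per state in general. Five patterns
are recognized syntactically (after rewriting, up to bound-variable
renaming) and answered by direct relation inspection instead:

| pattern | answered by |
|---|---|
| `down s . EX s` | self-loop states (`R ∧ diag`, or adjacency scan) |
| `down s . AX s` | self-loops minus states with ≥ 2 successors |
| `down s . EX EF s` | non-trivial SCCs (in-package Kosaraju) plus self-loops |
| `down s . EX ((not s) and EX s)` | `R ∧ R⁻¹` off the diagonal |
| `down s . EX down t . EY (s and EX not t)` | out-degree ≥ 2, one linear scan |

The multi-successor formula has no canonical spelling in the field; the
one fixed above holds at `s` iff `s` has a successor `t` witnessed by a
predecessor (`s` itself) with a successor other than `t`, i.e. iff `s`
has at least two distinct successors. Only this exact shape is
special-cased; any other body under `down σ . EX down τ . …` takes the
naive plan. Matching is deliberately syntactic — a semantically
equivalent formula takes the naive plan — so the plan chosen is always
predictable from the formula text. The out-degree scan counts each state
and each transition exactly once and records its work
(`relation.last_scan`), which the test suite asserts.

## Backends and the oracle

Two backends satisfy one state-set contract. The default is symbolic:
sets and the relation are reduced ordered BDDs built by a minimal
in-package engine (hash-consed nodes, memoized `ite`, existential
quantification, level renaming, model counting/enumeration). Variable
order interleaves current and next bits per gene in canonical order — the
standard layout for transition relations, keeping `R`'s per-gene
constraints local. The explicit backend stores adjacency sets and serves
as the in-contract reference up to 20 genes.

Independent of both, `grnmc.oracle` re-implements the semantics directly
on the enumerated digraph with plain Python sets — universal operators
from their own path semantics rather than via rewriting, binders by
literal per-state substitution, SCCs via networkx — and shares no set
algebra with the engine. The differential suite compares engine and
oracle set-for-set on 200 seeded random networks (sizes 3–8, in-degree
≤ 3, star probability 0 and 0.1, both modes) over a 28-formula battery
covering every operator and binder nesting to depth 2.

## Random networks

The generator draws, per gene, `k` distinct regulators and a uniform
truth table, starring each row independently with probability
`star_prob`. Defaults for the differential studies: in-degree 3, star
probability 0 or 0.1 (alternating), sizes cycling over 3–6 with a smaller
tail at 7–8. Sizes lean small by design: the enumerated oracle is the
expensive side of every comparison, and regulatory motifs of this scale
are where hand-verifiable structure (fixed points, two-cycles, basins)
is densest. What these networks do *not* emulate: the degree
heterogeneity, canalizing bias and sparse truth tables of curated
biological models — so differential passes certify the *engine*, not any
biological claim; the packaged root stem-cell-niche model plays that
role.

## Numerical and degenerate-input choices

* Totality of the relation is guaranteed by construction (allowed sets
  are never empty), so `preimage(full) = full` is an invariant, not an
  assumption.
* Enumeration of result sets is capped (default 10 000 rows) but counts
  are always exact (BDD model counting / set cardinality).
* `0`/`1` are accepted as constant atoms in equation bodies so that
  clamped (perturbed) networks round-trip through the equation dialect;
  genes referenced but never defined are an error, never implicit
  inputs.
* Table files must be complete (every regulator combination exactly
  once); silent defaults would mask modeling errors.
* A one-gene network is the smallest valid model; `A := A;` yields two
  fixed points, `A := ~A;` a synchronous two-cycle (asynchronously, two
  states with forced exits and no self-loops).

## The packaged root model and its variants

`root_scn.eq` carries the nine printed equations; all rules are
deterministic and the asynchronous analysis yields seven stable steady
states, the four auxin-active ones matching the niche cell-type profiles
gene for gene. `root_scn_scr_star.tables` keeps the one indeterminate SCR
row (SHR=1, SCR=1, JKD=0, MGP=1 → `*`): the equation model's SCR rule
equals this table's star→0 resolution, and both resolutions are available
(`root_scn_scr_star_resolved`). Because no fixed point hits the starred
row — it forces JKD to flip — the stable set is provably unchanged by the
star, and no state self-loops with an exit there either (JKD cannot
hold), so the variant adds branching without adding steady states.
`root_scn_fas0.tables` stars every SCR row (the fas mutant): all four
niche profiles persist as unstable steady states.

## Known limitations

* Genes are strictly Boolean; no multi-valued levels, priority classes,
  or partially asynchronous schedules.
* No counterexample/witness paths — results are state sets only.
* The BDD engine has no garbage collection or dynamic reordering; it is
  sized for networks of a few dozen genes, not for the 10^20-state
  regime industrial checkers target.
* `attractor_states` implements the cycle-membership notion (any state
  on a cycle, including non-terminal ones); `terminal_attractors` is the
  terminal-SCC notion. They differ whenever a cycle can be escaped —
  conflating them misreads perturbation screens.
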