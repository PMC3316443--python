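# grnmc — set-returning model checking for Boolean gene regulatory networks

`grnmc` analyzes Boolean gene regulatory networks (GRNs) whose update rules
may be **indeterminate**: a gene's rule can allow more than one next value,
either because two equations share a left-hand side or because a truth-table
row carries a `*`. Indeterminations capture asynchrony, incompletely known
regulation, and unpredictable environmental inputs — all of which give a
state *more than one possible future*. Simulators can only sample such
branching state spaces; a branching-time model checker can prove properties
over all of the infinitely many paths at once, and `grnmc` additionally
*returns the full set of states* satisfying a query rather than a yes/no
answer for a given initial state.

The logic is CTL (path quantifiers **E**/**A** over **X**/**F**/**G**/**U**)
extended with three things plain CTL cannot express steady states with:

* the hybrid binder `down σ . φ`, which binds the state variable σ to the
  current evaluation state — so `down s . AX s` is the set of **stable
  steady states** (only transition: the self-loop), `down s . EX s` adds
  the **unstable steady states** (self-loop plus exits), `down s . EX EF s`
  is the set of states on a cycle (**attractors of any size**), and
  `down s . EX ((not s) and EX s)` the states in **size-two attractors**;
* the past operator `EY` (Exists Yesterday — some predecessor satisfies
  the operand), which lets the checker act as a forward stepper;
* state literals `#k`, naming the state whose index, read in binary with
  the lexicographically first gene as the most significant bit, is `k`.

Evaluation uses the standard labeling algorithm (Boolean operators as set
algebra, `EX` as one reverse traversal, `EF`/`EG`/`EU` as fixpoints),
state sets represented as reduced ordered BDDs built by a small in-package
engine; an explicit-enumeration backend and an independent brute-force
oracle cross-check every operator. Binder formulas cost one labeling run
per state, except five common patterns that are answered by direct
relation inspection (see `docs/methods.md`).

## Worked example: the A. thaliana root stem-cell-niche network

The packaged nine-gene model couples the auxin pathway (AUXINS ⊣ IAA ⊣ ARF
→ PLT) to the SHR/SCR module with its JKD/MGP/WOX5 feedbacks
(`src/grnmc/data/root_scn.eq`). Under asynchronous updates:

```sh
$ grnmc check --model src/grnmc/data/root_scn.eq \
        --recipe stable-steady-states --mode async --format tsv
state_index	ARF	AUXINS	IAA	JKD	MGP	PLT	SCR	SHR	WOX
64	0	0	1	0	0	0	0	0	0
66	0	0	1	0	0	0	0	1	0
118	0	0	1	1	1	0	1	1	0
392	1	1	0	0	0	1	0	0	0
394	1	1	0	0	0	1	0	1	0
431	1	1	0	1	0	1	1	1	1
446	1	1	0	1	1	1	1	1	0
```

Seven stable steady states; the four with active auxin signaling
(AUXINS = 1) are exactly the expected expression profiles of the niche
cell types: state 431 is the quiescent center (SCR, JKD, WOX5 on, MGP
off), 446 the cortex/endodermis initials (MGP on, WOX5 off), 394 the
vascular initials (SHR on, SCR off) and 392 the epidermis/root-cap
initials (SHR off). The same query as a raw formula is
`--formula "down s . AX s"`.

Keeping the indeterminate row of the SCR truth table
(`root_scn_scr_star.tables`: SCR may or may not stay expressed when
SHR = SCR = 1, JKD = 0, MGP = 1) leaves these seven states unchanged,
while the fas-mutant model (`root_scn_fas0.tables`, every SCR row
indeterminate) keeps all four niche profiles as steady states — now
self-loops with exits, reported by `--recipe steady-states` (count 9).
Perturbation screens are one flag: `--perturb JKD=0` clamps JACKDAW off
and drops the quiescent-center and cortex/endodermis attractors.

Basins and conditional reachability work the same way, e.g. the basin of
the quiescent center: `--recipe basin --target "#431"`, or "reach the
quiescent center without passing through states where WOX5 is off":
`--formula "E[(WOX) U #431]"`.

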