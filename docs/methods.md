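# Methods

## Discrete model

Each entity *n* has levels `Z_n = {0,…,r_n}` (all case-study entities
are Boolean, `r_n = 1`; multivalued networks are exercised by the
synthetic generators).  An interaction `a → b` carries a threshold
`j ∈ [1, r_a]` and a sign.  In state *x* the **resource set** of *n* is

    R_n(x) = { a regulator of n :  (a activates n and x_a ≥ j)
                                or (a inhibits n and x_a < j) }

i.e. an inhibitor contributes by *absence*.  A total table
`K_n : 2^regulators → Z_n` (the logical parameters) assigns the level
*n* tends toward.  Evolution is asynchronous and unit-step: state *x*
has one successor per entity with `x_n ≠ K_n(R_n(x))`, moving that
entity one unit toward its target.  The state graph is built over the
full product space (a configurable cap, default 2^20 states, guards
blow-up); a state is a fixed point (deadlock) iff every entity sits at
its target.

Coordinate convention: states are tuples ordered
(IGF-1R/EGFR, ER-α, BRCA1, p53, Mdm2).  All printed tuples follow it.

### The ambiguous edge sign

The case-study wiring fixes six of its seven signs (receptor activates
ER-α; ER-α and Mdm2 inhibit p53; BRCA1 activates p53; p53 activates
BRCA1 and Mdm2).  The sign of p53 → ER-α is genuinely open, so
`casestudy.confirm_sign_assignment()` brute-forces both options against
the reference dynamic facts: the metastatic deadlock `(1,1,0,0,0)` and
its reachability from rest, cycles confined to zones P1/P2a/P2b with
none in P3, at least one oscillation crossing P1 ↔ P2a, and the P2b
oscillation self-contained.  Exactly one option (activation) survives;
the pipeline raises if zero or both do.

### The cycle count

The reference analysis reports 75 cyclic trajectories.  This number is
not derivable from the selected network under the semantics above.  We
verified exhaustively: both candidate signs give 7 and 2 elementary
cycles respectively; across all 128 sign assignments of the seven
edges, no assignment consistent with the published deadlock exceeds 7;
across all 131,072 parameter tables under the canonical signs, graphs
with exactly 75 elementary cycles exist but none has the published
deadlock and none matches the selected table (all force the receptor
input to decay, contradicting its parameter `K = 1`).  Alternative
cycle identities (rooted rather than rotation-canonical cycles: 36;
edge-simple closed trails: 36; synchronous updates: 1;
any-subset asynchronous updates: 242; simple or edge-simple paths from
rest to the deadlock: 39 / 82) do not produce 75 either.  The package
therefore treats elementary directed cycles up to rotation as the cycle
identity, reports the computed 7, and keeps the published 75 in the
fixture file so the comparison surfaces the discrepancy explicitly
instead of hiding it.  Every *qualitative* published claim about the
cycles is reproduced: they lie in P1 ∪ P2a ∪ P2b only, allow passage
between P1 and P2a, keep P2b to itself, and avoid P3 entirely.

A second fixed point, `(1,1,1,1,1)`, follows from the parameter
arithmetic (BRCA1 alone is a sufficient p53 resource); the narrative
around the reference analysis discusses only the metastatic deadlock,
so the fixture asserts membership of `(1,1,0,0,0)`, not uniqueness.

### Zones

The risk-zone rule is configuration, not code: ordered first-match
blocks keyed on marker levels.  The shipped scheme is P1 = receptor off
and ER-α off; P2a = receptor off, ER-α on; P3 = both on, *except* that
states with p53 on and BRCA1 off fall through to P2b; P2b = the rest.
The p53/BRCA1 exception is the only rule reproducing the reference
state lists (sizes 8/8/10/6); its biological intent is undocumented, so
it is confined to the scheme file.  A fixture mode returns the printed
partition verbatim.

## CTL checking

Standard bottom-up fixpoint labeling over the finite state graph.
Deadlock (finite-path) conventions: `EX φ` is false and `AX φ`
vacuously true at states without successors; a maximal path ending in a
deadlock counts as a full path, so `AG φ` can hold on a terminating
trajectory and `AF φ` at a deadlock requires `φ` there.  Operationally:
`E[φ U ψ]` and `EF` are least fixpoints by backward chaining; `A[φ U ψ]`
(and `AF`) additionally require at least one successor at non-goal
states; `EG` is a greatest fixpoint in which deadlocked `φ`-states
remain.  The dualities `AX = ¬EX¬`, `AG = ¬EF¬`, `AF = ¬EG¬` hold under
these conventions and are property-tested, as is agreement with an
independent explicit-path oracle on random graphs.  Comparators beyond
equality (`>=`, `<`, …) exist for multivalued synthetic networks; the
case study needs only `=`.

## Parameter synthesis

Candidates are the product over entities of all total tables; the
stream is lazy, duplicate-free, deterministic (entities in declaration
order, resource sets by size then name, values ascending), and capped
(default 2^21, with the computed count in the error).  Optional
entity-local constraints prune tables before any graph is built:
Snoussi monotonicity (`R1 ⊆ R2 ⇒ K(R1) ≤ K(R2)`) and observability
(every regulator changes some K value).  Both default to off, since the
reference workflow does not document which options were used; the
selected case-study table satisfies both.  Filtering builds each
candidate's state graph on demand and model-checks the given formulas,
either at user-supplied initial states (default) or at all states.  The
exact CTL properties behind the published "five accepted parameter
sets" live only in an external supplementary file; when it is absent
the five-set check reports SKIPPED, and the always-on surrogate is that
the selected table survives filtering by properties true of its own
graph (e.g. reachability of the metastatic deadlock).

## Continuous model

Mass-action rate of a transition: `k · Π m_p^w` over its normal and
test input places; normal inputs are consumed, test inputs are not;
an inhibitory arc gates the rate to zero once its place reaches the arc
weight.  The ODE engine (LSODA, rtol 1e-6, atol 1e-9, dense output on a
uniform 1,001-point grid) regularizes each inhibitory gate with a
narrow linear ramp (default 1e-3 tokens) because self-limiting loops
settle *exactly at* the gate threshold, and a discontinuous step there
is a sliding-mode equilibrium that stalls step-size control; the ramp
biases plateaus by at most its own width.  A steep-Hill smooth gate is
available as an alternative.  The stochastic engine is a Gillespie-type
simulator with unit token quanta and exponential waiting times from the
same propensities; averaging runs (seeded, reproducible) converges to
the ODE solution, which tests verify on a decay net and on the disease
variant.

### Case-study topologies

The two seven-place variants (ligand, receptor, complex, ER-α, BRCA1,
p53, Mdm2; 8 transitions and 18 arcs each; ligand/receptor start at 5
tokens; all rates 1) are reconstructions committed as config data — the
reference diagrams are not machine-readable, so the wiring is one
consistent realization of the documented behavioral contract, and
alternatives can be swapped in without touching code.

*Homeostatic*: binding consumes ligand and receptor into the complex;
complex signaling (test arcs) produces ER-α and p53, both gated off by
Mdm2 (weight 1); p53 drives BRCA1 (self-limited at 2) and Mdm2
(self-limited at 5); ER-α degrades; ligand and receptor clear.  Result:
ER-α → 0 below every tumor suppressor; p53 freezes near 2.4 when the
Mdm2 gate closes; Mdm2 → 5.

*Pathological*: the inhibition is redirected — ER-α gates p53
production, no feedback reaches ER-α — and the ligand → complex → ER-α
chain is conservative (no ER-α sink), so ligand + complex + ER-α is an
exact invariant and ER-α's asymptote equals the initial stock of 5.
ER-α drives receptor re-expression (self-limited at 3), keeping the
receptor pool elevated while the tumor suppressors stay at zero.

### Sign matrix

The qualitative comparison assigns, per entity, "+" to the condition
with the higher plateau (trailing 20% of the trace) and "−" to the
other, upgrading "+" to "++" when the winning plateau reaches 80% of
the 5-token stock; plateau ties (both conditions drained, e.g. the
ligand) are broken by total exposure, the time-averaged level over the
whole horizon.  Under this rule the computed matrix matches the
reference matrix row for row.

## Synthetic generators

`random_brn` draws each ordered entity pair independently at the
requested edge density (self-loops off by default, as in the case
study), with uniform signs and thresholds; `random_parameterization`
draws values per resource set, propagating maxima up the inclusion
lattice when monotonicity is requested.  All generation is
seed-deterministic with no global state.  The motif library (toggle
switch, negative loop, input chain, p53–Mdm2 oscillator) carries
machine-checkable expectation records (fixed points, cycle presence)
that the test suite re-derives through the main pipeline.  What the
generators emulate is the *structure* the analysis assumes — signed
thresholded regulation with total parameter tables — not biologically
realistic topology (no scale-free degree statistics, no hub bias), so
passing tests certify the algorithms, not topological realism.

## Problem sizes and numerics

Test and acceptance workloads are desk-scale by design: the 32-state
case study is exact and instantaneous; oracle-equivalence suites use
random graphs of ≤ 12 nodes (cycles) and ≤ 8 nodes (CTL) with fixed
seeds; synthesis tests filter the monotone+observable candidate space
(36 tables) rather than all 131,072, whose size is still verified
combinatorially and by streaming; stochastic-convergence tests use a
two-place decay net at 10–400 runs and the disease net at 50–60 runs.
Trace CSV is written at 12 significant digits (round-trips to 1e-9);
graph exports (DOT, GraphML) use canonical state-tuple labels and
sorted node order, so all writers are byte-deterministic.

## Known limitations

Synchronous or priority-class updates, LTL/CTL*, fairness, BDD-based
synthesis, Michaelis–Menten kinetics (hook reserved) and Petri-net
structural theory are out of scope.  The published cycle total (75) and
the exact CTL property file behind the five accepted parameter sets
could not be independently reproduced or obtained; both are surfaced as
explicit fixture outcomes (mismatch and SKIPPED respectively) rather
than absorbed.
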