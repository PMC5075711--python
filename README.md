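# thomasnet

Kinetic-logic modeling of biological regulatory networks, with the
ER-α–associated breast-cancer network as a fully analyzed case study.

Breast-cancer metastasis is driven, in one well-studied route, by the
interplay of the growth-factor receptors IGF-1R/EGFR, the estrogen
receptor ER-α, and the tumor suppressors BRCA1, p53 and Mdm2: receptor
signaling raises ER-α, ER-α suppresses p53, and p53 feeds back through
BRCA1 (activation) and Mdm2 (inhibition).  `thomasnet` asks what such a
wiring diagram can *do* — which qualitative states are reachable, which
oscillations sustain homeostasis, and which trajectories lock the cell
into a metastatic phenotype — using two complementary formalisms:

* **Discrete kinetic logic (René Thomas formalism).**  Each entity *n*
  takes levels in `{0,…,r_n}`; each edge carries a threshold and a sign.
  In a state *x*, the *resources* of *n* are the regulators currently
  helping it (activators at/above threshold, inhibitors below), and a
  logical-parameter table `K_n(resources)` gives the level *n* tends
  toward.  The asynchronous state graph moves one entity one unit per
  transition; its fixed points and elementary cycles are the
  qualitative phenotypes.  CTL model checking (`EX/EF/EG/AX/AF/AG/EU/AU`
  by fixpoint labeling) both queries these dynamics and drives
  *parameter synthesis*: enumerate all candidate tables, keep those
  whose dynamics satisfy given temporal-logic observations.
* **Continuous hybrid Petri nets.**  Places hold real token markings,
  transitions fire at mass-action rates, test arcs read without
  consuming, inhibitory arcs gate a transition off at their weight.  A
  deterministic ODE engine and a run-averaged stochastic engine share
  one model description; two seven-place variants contrast homeostasis
  (tumor-suppressor feedback intact) with disease (inhibition
  redirected onto p53).

The library is the interface: import it from Python, or run the short
narrative scripts in `examples/`.

## Worked example

```python
from thomasnet import casestudy as cs
from thomasnet.analysis import enumerate_elementary_cycles, find_deadlocks
from thomasnet.brn import build_state_graph

brn, k = cs.load_reference_network()
graph = build_state_graph(brn, k)
print(graph.n_states)                      # 32
print(sorted(find_deadlocks(graph)))       # [(1, 1, 0, 0, 0), (1, 1, 1, 1, 1)]
print(len(enumerate_elementary_cycles(graph)))  # 7
```

The 32 states are the full Boolean product space over
(IGF-1R/EGFR, ER-α, BRCA1, p53, Mdm2).  The deadlock `(1,1,0,0,0)` is
the metastatic end-state — both cancer markers locked on, every tumor
suppressor silenced — and it is reachable from the resting state
`(0,0,0,0,0)`.  The 7 elementary cycles are the sustained p53–Mdm2
oscillations; all of them stay inside the low/medium-risk zones
(P1/P2a/P2b, of sizes 8/8/10), and none touches the metastatic zone P3
(6 states), which only drains toward the deadlock.

Continuing with the continuous model:

```python
rep = cs.run_continuous_analysis()
print(rep.plateaus["ER-alpha"])   # {'homeostasis': 0.0, 'disease': 5.0}
print(rep.sign_matrix["p53"])     # {'homeostasis': '+', 'disease': '-'}
```

Under disease wiring the conservative ligand → complex → ER-α chain
drives ER-α to the full initial stock of 5 tokens while p53, BRCA1 and
Mdm2 decay to zero; under homeostatic wiring Mdm2 feedback pins ER-α
near zero below every tumor suppressor.  `examples/04_hpn_simulation.py`
prints the full plateau table and sign matrix.

A note on the published cycle total: the reference analysis reports 75
cyclic trajectories for this network.  Exhaustive recomputation under
asynchronous unit-step semantics — over both candidate signs of the one
ambiguous edge and all 131,072 parameter tables — shows the selected
network has exactly 7 elementary cycles, and no parameterization
consistent with the published deadlock has 75.  The pipeline therefore
reports the computed 7 and flags the 75 as a fixture mismatch rather
than adjusting either number; see `docs/methods.md`.

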