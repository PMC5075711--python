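"""CTL model checking over the case-study state graph.

Temporal-logic queries: which states can still reach the metastatic
deadlock, which can keep oscillating forever, and a concrete witness
trajectory into metastasis.
"""

from thomasnet import casestudy as cs
from thomasnet.brn import build_state_graph
from thomasnet.ctl import parse_formula, satisfying_states, witness_path

brn, k = cs.load_reference_network()
graph = build_state_graph(brn, k)

queries = {
    "can reach metastasis": "EF(IGF-1R/EGFR=1 & ER-alpha=1 & BRCA1=0 & p53=0 & Mdm2=0)",
    "doomed to metastasis": "AF(IGF-1R/EGFR=1 & ER-alpha=1 & BRCA1=0 & p53=0 & Mdm2=0)",
    "p53 can switch on": "EF(p53=1)",
    "tumor suppression alive forever (some path)": "EG(ER-alpha=0)",
}
for label, text in queries.items():
    sat = satisfying_states(graph, parse_formula(text))
    print(f"{label}: {len(sat)}/32 states satisfy {text}")

goal = frozenset({(1, 1, 0, 0, 0)})
path = witness_path(graph, goal, (0, 0, 0, 0, 0))
print("\nshortest trajectory from rest into the metastatic deadlock:")
for state in path:
    print("  ", state)
print("each step flips exactly one entity one level toward its target.")
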