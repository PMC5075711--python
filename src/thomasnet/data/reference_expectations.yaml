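# Reference expectations for the ER-alpha case study, used by
# compare_to_fixtures.  Coordinate order: IGF-1R/EGFR, ER-alpha, BRCA1,
# p53, Mdm2.
#
# The reported cycle count of 75 is retained here verbatim as the
# published reference value.  Under Thomas asynchronous semantics the
# selected network has exactly 7 elementary cycles (see
# docs/methods.md); the pipeline therefore reports this fixture as a
# mismatch rather than silently adjusting either number.
schema_version: 1
kind: reference-expectations
initial_state: [0, 0, 0, 0, 0]
deadlock_state: [1, 1, 0, 0, 0]
n_states: 32
n_cycles_reported: 75
# Qualitative sign matrix for the continuous comparison: per entity,
# one sign per condition ("-" low, "+" raised, "++" over-expressed).
table2_signs:
  IGF-1/EGF: {homeostasis: "-", disease: "+"}
  IGF-1R/EGFR: {homeostasis: "-", disease: "+"}
  ER-alpha: {homeostasis: "-", disease: "++"}
  BRCA1: {homeostasis: "+", disease: "-"}
  p53: {homeostasis: "+", disease: "-"}
  Mdm2: {homeostasis: "++", disease: "-"}
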