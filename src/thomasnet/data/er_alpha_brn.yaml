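# ER-alpha associated regulatory network (breast-cancer case study).
# Five Boolean entities in fixed coordinate order; seven signed edges,
# all thresholds 1; the selected logical-parameter set.
# The p53 -> ER-alpha activation is the configuration confirmed by the
# two-way sign oracle in thomasnet.casestudy (the alternative inhibitory
# reading fails the reference dynamic facts).
schema_version: 1
kind: brn
name: er-alpha-brn
entities:
  - {name: IGF-1R/EGFR, max_level: 1}
  - {name: ER-alpha, max_level: 1}
  - {name: BRCA1, max_level: 1}
  - {name: p53, max_level: 1}
  - {name: Mdm2, max_level: 1}
interactions:
  - {source: IGF-1R/EGFR, target: ER-alpha, sign: "+", threshold: 1}
  - {source: p53, target: ER-alpha, sign: "+", threshold: 1}
  - {source: ER-alpha, target: p53, sign: "-", threshold: 1}
  - {source: BRCA1, target: p53, sign: "+", threshold: 1}
  - {source: Mdm2, target: p53, sign: "-", threshold: 1}
  - {source: p53, target: BRCA1, sign: "+", threshold: 1}
  - {source: p53, target: Mdm2, sign: "+", threshold: 1}
parameters:
  - {entity: IGF-1R/EGFR, resources: [], value: 1}
  - {entity: ER-alpha, resources: [], value: 0}
  - {entity: ER-alpha, resources: [p53], value: 1}
  - {entity: ER-alpha, resources: [IGF-1R/EGFR], value: 1}
  - {entity: ER-alpha, resources: [IGF-1R/EGFR, p53], value: 1}
  - {entity: BRCA1, resources: [], value: 0}
  - {entity: BRCA1, resources: [p53], value: 1}
  - {entity: p53, resources: [], value: 0}
  - {entity: p53, resources: [ER-alpha], value: 0}
  - {entity: p53, resources: [Mdm2], value: 0}
  - {entity: p53, resources: [BRCA1], value: 1}
  - {entity: p53, resources: [ER-alpha, Mdm2], value: 1}
  - {entity: p53, resources: [ER-alpha, BRCA1], value: 1}
  - {entity: p53, resources: [BRCA1, Mdm2], value: 1}
  - {entity: p53, resources: [ER-alpha, BRCA1, Mdm2], value: 1}
  - {entity: Mdm2, resources: [], value: 0}
  - {entity: Mdm2, resources: [p53], value: 1}
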