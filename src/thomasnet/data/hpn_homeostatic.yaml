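# Homeostatic (normal) ER-alpha hybrid Petri net: 7 places, 8
# transitions, 18 arcs.  Receptor signaling (via the ligand-receptor
# complex, read by test arcs) raises p53 and thereby BRCA1 and Mdm2;
# Mdm2 negative feedback (inhibitory arcs) shuts down ER-alpha and
# further p53 production, keeping ER-alpha below every tumor
# suppressor.  Self-limiting inhibitory arcs cap BRCA1 and Mdm2.
# Ligand and receptor start at 5 tokens; every mass-action rate is 1.
schema_version: 1
kind: hpn
name: er-alpha-hpn
variant: homeostatic
places:
  - {name: IGF-1/EGF, kind: continuous, marking: 5}
  - {name: IGF-1R/EGFR, kind: continuous, marking: 5}
  - {name: Complex, kind: continuous, marking: 0}
  - {name: ER-alpha, kind: continuous, marking: 0}
  - {name: BRCA1, kind: continuous, marking: 0}
  - {name: p53, kind: continuous, marking: 0}
  - {name: Mdm2, kind: continuous, marking: 0}
transitions:
  - {name: bind, rate: 1}
  - {name: er_production, rate: 1}
  - {name: p53_production, rate: 1}
  - {name: brca1_production, rate: 1}
  - {name: mdm2_production, rate: 1}
  - {name: er_degradation, rate: 1}
  - {name: ligand_clearance, rate: 1}
  - {name: receptor_internalization, rate: 1}
arcs:
  # ligand + receptor -> complex
  - {source: IGF-1/EGF, target: bind, kind: normal, weight: 1}
  - {source: IGF-1R/EGFR, target: bind, kind: normal, weight: 1}
  - {source: bind, target: Complex, kind: normal, weight: 1}
  # complex signaling drives ER-alpha, gated off by Mdm2 feedback
  - {source: Complex, target: er_production, kind: test, weight: 1}
  - {source: Mdm2, target: er_production, kind: inhibitory, weight: 1}
  - {source: er_production, target: ER-alpha, kind: normal, weight: 1}
  # complex signaling drives p53, gated off by Mdm2 feedback
  - {source: Complex, target: p53_production, kind: test, weight: 1}
  - {source: Mdm2, target: p53_production, kind: inhibitory, weight: 1}
  - {source: p53_production, target: p53, kind: normal, weight: 1}
  # p53 stimulates BRCA1, self-limited at 2
  - {source: p53, target: brca1_production, kind: test, weight: 1}
  - {source: BRCA1, target: brca1_production, kind: inhibitory, weight: 2}
  - {source: brca1_production, target: BRCA1, kind: normal, weight: 1}
  # p53 stimulates Mdm2, self-limited at 5
  - {source: p53, target: mdm2_production, kind: test, weight: 1}
  - {source: Mdm2, target: mdm2_production, kind: inhibitory, weight: 5}
  - {source: mdm2_production, target: Mdm2, kind: normal, weight: 1}
  # turnover
  - {source: ER-alpha, target: er_degradation, kind: normal, weight: 1}
  - {source: IGF-1/EGF, target: ligand_clearance, kind: normal, weight: 1}
  - {source: IGF-1R/EGFR, target: receptor_internalization, kind: normal, weight: 1}
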