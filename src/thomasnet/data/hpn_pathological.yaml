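# Pathological (disease) ER-alpha hybrid Petri net: 7 places, 8
# transitions, 18 arcs.  The inhibition is redirected: ER-alpha now
# suppresses p53 production and no tumor-suppressor feedback reaches
# ER-alpha.  The ligand -> complex -> ER-alpha chain is conservative
# (ER-alpha has no sink), so ER-alpha climbs to the full initial
# ligand stock of 5 while the tumor suppressors stay silenced.
# ER-alpha also drives receptor over-expression, self-limited at 3,
# continually replenishing the receptor pool.
# Ligand and receptor start at 5 tokens; every mass-action rate is 1.
schema_version: 1
kind: hpn
name: er-alpha-hpn
variant: pathological
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
  - {name: receptor_expression, rate: 1}
  - {name: p53_production, rate: 1}
  - {name: brca1_production, rate: 1}
  - {name: mdm2_production, rate: 1}
  - {name: p53_degradation, rate: 1}
  - {name: mdm2_degradation, rate: 1}
arcs:
  # ligand and receptor consumed into the signaling complex
  - {source: IGF-1/EGF, target: bind, kind: normal, weight: 1}
  - {source: IGF-1R/EGFR, target: bind, kind: normal, weight: 1}
  - {source: bind, target: Complex, kind: normal, weight: 1}
  # complex converts to ER-alpha with no sink: conservative chain
  - {source: Complex, target: er_production, kind: normal, weight: 1}
  - {source: er_production, target: ER-alpha, kind: normal, weight: 1}
  # ER-alpha drives receptor over-expression, self-limited at 3
  - {source: ER-alpha, target: receptor_expression, kind: test, weight: 1}
  - {source: IGF-1R/EGFR, target: receptor_expression, kind: inhibitory, weight: 3}
  - {source: receptor_expression, target: IGF-1R/EGFR, kind: normal, weight: 1}
  # p53 production requires BRCA1 and is blocked by ER-alpha (redirected
  # inhibition)
  - {source: BRCA1, target: p53_production, kind: test, weight: 1}
  - {source: ER-alpha, target: p53_production, kind: inhibitory, weight: 1}
  - {source: p53_production, target: p53, kind: normal, weight: 1}
  # p53 feedback onto the other tumor suppressors
  - {source: p53, target: brca1_production, kind: test, weight: 1}
  - {source: brca1_production, target: BRCA1, kind: normal, weight: 1}
  - {source: p53, target: mdm2_production, kind: test, weight: 1}
  - {source: mdm2_production, target: Mdm2, kind: normal, weight: 1}
  # tumor-suppressor turnover; Mdm2 catalyzes p53 degradation
  - {source: p53, target: p53_degradation, kind: normal, weight: 1}
  - {source: Mdm2, target: p53_degradation, kind: test, weight: 1}
  - {source: Mdm2, target: mdm2_degradation, kind: normal, weight: 1}
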