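# Risk-zone scheme and reference partition for the 32-state ER-alpha
# state graph.  P1: neither cancer marker active (low risk); P2a/P2b:
# exactly one of ER-alpha / IGF-1R/EGFR persistently active (high risk);
# P3: both active (metastatic).  States with p53 on and BRCA1 off are
# kept out of P3 even when both markers are on (they fall to P2b),
# reproducing the reference state lists.
schema_version: 1
kind: zone-scheme
name: er-alpha-zones
blocks:
  - name: P1
    where: {IGF-1R/EGFR: 0, ER-alpha: 0}
  - name: P2a
    where: {IGF-1R/EGFR: 0, ER-alpha: 1}
  - name: P3
    where: {IGF-1R/EGFR: 1, ER-alpha: 1}
    exclude:
      - {p53: 1, BRCA1: 0}
  - name: P2b
    otherwise: true
# Reference state lists (coordinate order IGF-1R/EGFR, ER-alpha, BRCA1,
# p53, Mdm2); sizes 8 / 8 / 10 / 6.
reference_partition:
  P1:
    - [0, 0, 0, 0, 0]
    - [0, 0, 0, 1, 0]
    - [0, 0, 0, 1, 1]
    - [0, 0, 1, 1, 1]
    - [0, 0, 1, 0, 1]
    - [0, 0, 1, 0, 0]
    - [0, 0, 1, 1, 0]
    - [0, 0, 0, 0, 1]
  P2a:
    - [0, 1, 1, 1, 0]
    - [0, 1, 0, 1, 0]
    - [0, 1, 0, 1, 1]
    - [0, 1, 1, 1, 1]
    - [0, 1, 1, 0, 1]
    - [0, 1, 0, 0, 1]
    - [0, 1, 1, 0, 0]
    - [0, 1, 0, 0, 0]
  P2b:
    - [1, 0, 0, 0, 1]
    - [1, 0, 0, 0, 0]
    - [1, 0, 0, 1, 0]
    - [1, 0, 0, 1, 1]
    - [1, 0, 1, 1, 1]
    - [1, 0, 1, 0, 1]
    - [1, 0, 1, 0, 0]
    - [1, 0, 1, 1, 0]
    - [1, 1, 0, 1, 0]
    - [1, 1, 0, 1, 1]
  P3:
    - [1, 1, 1, 1, 0]
    - [1, 1, 1, 1, 1]
    - [1, 1, 1, 0, 1]
    - [1, 1, 1, 0, 0]
    - [1, 1, 0, 0, 1]
    - [1, 1, 0, 0, 0]
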