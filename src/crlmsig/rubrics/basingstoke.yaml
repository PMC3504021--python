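# Basingstoke predictive index (Rees, 2008), dichotomized at >= 10.
# Weights transcribed approximately from the original publication; the
# extrahepatic-disease criterion ships disabled because the modelled
# cohort excludes extrahepatic disease (the index is then structurally
# incomplete).  Review weights against the reference before clinical use.
name: basingstoke
high_risk_threshold: 10
criteria:
  - label: node-positive primary
    field: nodal_status
    op: eq
    value: positive
    points: 3
  - label: poorly differentiated primary
    field: differentiation
    op: eq
    value: poor
    points: 3
  - label: more than three metastases
    field: n_metastases
    op: gt
    value: 3
    points: 3
  - label: largest metastasis >= 5 cm
    field: largest_metastasis_cm
    op: ge
    value: 5
    points: 3
  - label: preoperative CEA > 60 ng/ml
    field: preop_cea
    op: gt
    value: 60
    points: 3
  - label: positive resection margin (R1)
    field: margin
    op: eq
    value: R1
    points: 3
  - label: extrahepatic disease
    field: null
    op: always
    value: null
    points: 4
    enabled: false
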