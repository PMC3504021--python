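# Nordlinger prognostic score (Association Francaise de Chirurgie, 1996).
# Seven factors, 1 point each; dichotomized here at >= 4 points (high risk).
# Component criteria transcribed from the original publication; the
# serosal-invasion factor of the primary is approximated by TNM stage
# group >= 2 because T stage is not carried on ClinicalRecord — review
# against the reference before clinical use.
name: nordlinger
high_risk_threshold: 4
criteria:
  - label: age >= 60 years
    field: age
    op: ge
    value: 60
    points: 1
  - label: extension of primary into serosa (stage group >= 2 proxy)
    field: primary_stage
    op: ge
    value: 2
    points: 1
  - label: node-positive primary
    field: nodal_status
    op: eq
    value: positive
    points: 1
  - label: interval to metastasis < 24 months
    field: interval_to_metastasis
    op: lt
    value: 24
    points: 1
  - label: four or more metastases
    field: n_metastases
    op: ge
    value: 4
    points: 1
  - label: largest metastasis >= 5 cm
    field: largest_metastasis_cm
    op: ge
    value: 5
    points: 1
  - label: positive resection margin (R1)
    field: margin
    op: eq
    value: R1
    points: 1
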