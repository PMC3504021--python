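# Fong clinical risk score (Memorial Sloan-Kettering, 1999).
# Five factors, 1 point each; high risk at >= 3 points.
# Criteria transcribed from the original publication.
name: fong
high_risk_threshold: 3
criteria:
  - label: node-positive primary
    field: nodal_status
    op: eq
    value: positive
    points: 1
  - label: disease-free interval < 12 months
    field: interval_to_metastasis
    op: lt
    value: 12
    points: 1
  - label: more than one metastasis
    field: n_metastases
    op: gt
    value: 1
    points: 1
  - label: largest metastasis > 5 cm
    field: largest_metastasis_cm
    op: gt
    value: 5
    points: 1
  - label: preoperative CEA > 200 ng/ml
    field: preop_cea
    op: gt
    value: 200
    points: 1
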