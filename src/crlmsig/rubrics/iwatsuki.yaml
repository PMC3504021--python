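# Iwatsuki risk grade (Pittsburgh, 1999).
# Grade = 1 + number of risk factors present (grade 1 = no factors);
# high risk at grade >= 3, i.e. two or more factors.  The constant
# baseline criterion keeps the total on the grade scale so the published
# threshold applies directly.  Transcribed from the original publication.
name: iwatsuki
high_risk_threshold: 3
criteria:
  - label: baseline grade
    field: null
    op: always
    value: null
    points: 1
  - label: three or more metastases
    field: n_metastases
    op: ge
    value: 3
    points: 1
  - label: largest metastasis > 8 cm
    field: largest_metastasis_cm
    op: gt
    value: 8
    points: 1
  - label: interval to metastasis <= 30 months
    field: interval_to_metastasis
    op: le
    value: 30
    points: 1
  - label: bilobar distribution
    field: distribution
    op: eq
    value: bilobar
    points: 1
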