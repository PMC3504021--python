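# Mayo Clinic recurrence score (Zakaria, 2007), dichotomized at >= 2.
# Hepatoduodenal nodal involvement dominates (2 points); when its status
# is unrecorded — as in the cohort this package models — the total
# cannot exceed 2 and completeness is flagged false.  Component criteria
# transcribed approximately from the original publication; review before
# clinical use.
name: mayo
high_risk_threshold: 2
criteria:
  - label: positive hepatoduodenal lymph nodes
    field: hepatoduodenal_nodes
    op: eq
    value: positive
    points: 2
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
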