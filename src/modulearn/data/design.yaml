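# Default cohort design: a retest control cohort and three training cohorts.
# Each schedule entry is one 3-month period; RCC has an empty schedule and is
# assessed as "Retest" in every period.
RCC:
  size: 90
  schedule: []
TC1:
  size: 80
  schedule: [Presence, Affect, Perspective]
TC2:
  size: 81
  schedule: [Presence, Perspective, Affect]
TC3:
  size: 81
  schedule: [Affect]
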