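# Generator config emulating the reference survey's gender strata:
# an established service (dms, awareness leads want) and a newly
# introduced one (dhcs, want leads awareness) drawn for the same
# respondents.  Probabilities follow the nested funnel model; see
# docs/methods.md.
seed: 7
segments:
  - label: {gender: Male}
    n: 1518
    p_aware: 0.871
    p_want_given_aware: 0.892
    p_want_given_unaware: 0.0
    p_adopt_given_aware_want: 0.551
  - label: {gender: Female}
    n: 1556
    p_aware: 0.864
    p_want_given_aware: 0.902
    p_want_given_unaware: 0.0
    p_adopt_given_aware_want: 0.594
services:
  dms: []          # use the segment probabilities above
  dhcs:            # new-service overrides: want exceeds awareness
    - label: {gender: Male}
      n: 1518
      p_aware: 0.531
      p_want_given_aware: 1.0
      p_want_given_unaware: 0.350
      p_adopt_given_aware_want: 0.104
    - label: {gender: Female}
      n: 1556
      p_aware: 0.487
      p_want_given_aware: 1.0
      p_want_given_unaware: 0.409
      p_adopt_given_aware_want: 0.088
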