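# Synthetic site profiles.
#
# element_params: per element class, [mean, sd] of minimum frequency (Hz),
# maximum frequency (Hz) and element duration (s), plus peak frequency (Hz)
# for the broadband classes measured that way (POP, CR). Values follow the
# published per-variant acoustic parameters; grunts are broadband and have no
# published frequency band, and pop/crack durations are not tabulated, so
# those entries are this package's documented choices consistent with the
# qualitative class definitions.
#
# typology_mixture: relative weights, normalised at load time. The
# tyrrhenian_like weights follow the printed per-typology sequence counts for
# the seven most frequent typologies; the residual 80 of 637 sequences are
# spread evenly over the six typologies reported only as "about 2.5% each".
#
# inter_element_interval: [mean, sd] seconds per typology. Printed "± 0" SDs
# are replaced by a small positive spread so generated gaps are not
# degenerate.
element_params: &default_element_params
  GU1: {min_freq: [295, 94], max_freq: [773, 61], duration: [0.040, 0.010]}
  GU2: {min_freq: [361, 83], max_freq: [584, 70], duration: [0.040, 0.010]}
  GU3: {min_freq: [216, 45], max_freq: [541, 78], duration: [0.040, 0.010]}
  GU4: {min_freq: [592, 71], max_freq: [868, 86], duration: [0.070, 0.060]}
  GR1: {min_freq: [200, 80], max_freq: [2000, 500], duration: [0.140, 0.090]}
  GR2: {min_freq: [200, 80], max_freq: [2200, 500], duration: [0.140, 0.090]}
  SQ:  {min_freq: [535, 204], max_freq: [892, 303], duration: [0.170, 0.070]}
  POP: {min_freq: [400, 100], max_freq: [2600, 400], duration: [0.030, 0.010],
        peak_freq: [813, 158]}
  CR:  {min_freq: [150, 50], max_freq: [7000, 800], duration: [0.010, 0.003],
        peak_freq: [1237, 279]}
  LFN: {min_freq: [256, 64], max_freq: [650, 97], duration: [0.084, 0.040]}

inter_element_interval: &default_intervals
  1:  [0.40, 0.30]
  2:  [0.11, 0.02]
  3:  [0.14, 0.02]
  4:  [0.13, 0.10]
  5:  [0.20, 0.05]
  6:  [0.45, 0.30]
  7:  [0.17, 0.02]
  8:  [0.59, 0.40]
  9:  [0.13, 0.02]
  10: [0.50, 0.30]
  11: [0.65, 0.20]
  12: [0.30, 0.10]
  13: [0.30, 0.20]

profiles:
  tyrrhenian_like:
    site: tyrrhenian
    n_sequences: 637
    typology_mixture:
      1: 340
      2: 78
      9: 36
      5: 27
      10: 26
      7: 25
      8: 25
      3: 13.3333
      4: 13.3333
      6: 13.3333
      11: 13.3333
      12: 13.3333
      13: 13.3333
    element_params: *default_element_params
    inter_element_interval: *default_intervals
    inter_sequence_gap: 120.0
  sicily_like:
    site: sicily
    n_sequences: 7
    typology_mixture:
      1: 6
      10: 1
    # Lower frequencies and shorter gulps than the Tyrrhenian profile,
    # emulating the reported direction of the between-site differences.
    element_params:
      <<: *default_element_params
      GU1: {min_freq: [230, 70], max_freq: [640, 120], duration: [0.031, 0.008]}
      SQ:  {min_freq: [470, 180], max_freq: [780, 250], duration: [0.150, 0.060]}
    inter_element_interval: *default_intervals
    inter_sequence_gap: 120.0
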