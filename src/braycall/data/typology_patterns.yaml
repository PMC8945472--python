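# The 13 stereotyped bray-call sequence typologies.
#
# Each record describes one pattern over element-class labels; matching uses
# label order only, never timing. "match_order" lists ids most-specific-first
# so that, e.g., a pair-repetition sequence is never swallowed by a
# single-element run.
#
# Kinds:
#   single_element_run          one class repeated n times, n in run_range
#   pair_repetition             (A, B) repeated k times, per-role counts in range
#   triplet_repetition          (A, B, C) repeated k times, per-role counts in range
#   alternation                 strict single-element alternation of two classes,
#                               starting with either; per-role counts in range
#   run_alternation             runs of A alternating with runs of B (typology 5);
#                               constraints on total counts and number of A-runs
#   prefix_then_run             one prefix element then a run of another class
#   series_then_prefix_then_element   a run of A, then one B, then one C
match_order: [9, 6, 8, 12, 4, 2, 3, 5, 7, 11, 13, 1, 10]
patterns:
  - typology_id: 1
    kind: single_element_run
    roles: [GU1]
    run_range: [3, 105]
  - typology_id: 2
    kind: pair_repetition
    roles: [GU3, GU1]
    counts: {GU3: [2, 16], GU1: [2, 16]}   # 4-32 elements total
  - typology_id: 3
    kind: pair_repetition
    roles: [GU1, GU4]
    counts: {GU1: [8, 11], GU4: [3, 23]}
  - typology_id: 4
    kind: triplet_repetition
    roles: [GU1, GU2, GU3]
    counts: {GU1: [2, 22], GU2: [2, 20], GU3: [2, 22]}
  - typology_id: 5
    kind: run_alternation
    roles: [POP, GU1]
    counts: {POP: [9, 27], GU1: [1, 8]}
    series_range: [1, 16]                  # number of POP runs
  - typology_id: 6
    kind: prefix_then_run
    roles: [GR1, GU1]
    run_range: [6, 35]
  - typology_id: 7
    kind: alternation
    roles: [GR1, GU1]
    counts: {GR1: [3, 9], GU1: [3, 11]}
  - typology_id: 8
    kind: prefix_then_run
    roles: [GR2, GU1]
    run_range: [3, 26]
  - typology_id: 9
    kind: series_then_prefix_then_element
    roles: [CR, GR1, GU1]
    series_range: [2, 11]
  - typology_id: 10
    kind: single_element_run
    roles: [SQ]
    run_range: [2, 14]
  - typology_id: 11
    kind: alternation
    roles: [SQ, GU1]
    counts: {SQ: [2, 13], GU1: [2, 8]}
  - typology_id: 12
    kind: prefix_then_run
    roles: [SQ, GU1]
    run_range: [3, 27]
  - typology_id: 13
    kind: alternation
    roles: [LFN, GU1]
    counts: {LFN: [4, 6], GU1: [3, 17]}
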