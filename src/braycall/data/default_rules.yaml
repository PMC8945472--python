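# Default element-classification ruleset.
#
# Each record is one ClassifierRule. Categorical gates (sound_class, contour,
# harmonic) are evaluated before interval gates; "any" disables a gate.
# Interval gates on frequency/duration are mean +/- 2 SD around the published
# per-variant acoustic parameters; classes are primarily separated by their
# qualitative signatures (contour shape, harmonic-like structure, broad sound
# class), the intervals act as a sanity band.
#
# Gulp variants carry a spectrogram contour, so a file without a sound-class
# column (sound_class "unknown") can still be classified; grunts have no
# contour signature and therefore require an explicit pulsed_continuous
# sound class.
- target_class: GU1
  priority: 1
  sound_class: [pulsed_continuous, unknown]
  contour: [downsweep]
  harmonic: false
  min_freq: [107, 483]     # 295 +/- 2*94 Hz
  max_freq: [651, 895]     # 773 +/- 2*61 Hz
  duration: [0.02, 0.06]   # 0.04 +/- 2*0.01 s
- target_class: GU2
  priority: 2
  sound_class: [pulsed_continuous, unknown]
  contour: [flat]
  harmonic: true
  min_freq: [195, 527]     # 361 +/- 2*83 Hz
  max_freq: [444, 724]     # 584 +/- 2*70 Hz
  duration: [0.02, 0.06]
- target_class: GU3
  priority: 3
  sound_class: [pulsed_continuous, unknown]
  contour: [downsweep]
  harmonic: true
  min_freq: [126, 306]     # 216 +/- 2*45 Hz
  max_freq: [385, 697]     # 541 +/- 2*78 Hz
  duration: [0.02, 0.06]
- target_class: GU4
  priority: 4
  sound_class: [pulsed_continuous, unknown]
  contour: [flat]
  harmonic: false
  min_freq: [450, 734]     # 592 +/- 2*71 Hz
  max_freq: [696, 1040]    # 868 +/- 2*86 Hz
  duration: [0.0, 0.19]    # 0.07 +/- 2*0.06 s, floored at 0
- target_class: GR1
  priority: 5
  sound_class: [pulsed_continuous]
  contour: [none]
  harmonic: false
  duration: [0.04, 0.38]   # spans 0.11-0.18 +/- 2 SD across sequence contexts
- target_class: GR2
  priority: 6
  sound_class: [pulsed_continuous]
  contour: [none]
  harmonic: true
  duration: [0.0, 0.32]    # 0.14 +/- 2*0.09 s
- target_class: SQ
  priority: 7
  sound_class: [pulsed_tonal]
  contour: any
  harmonic: any
  min_freq: [127, 943]     # 535 +/- 2*204 Hz
  max_freq: [286, 1498]    # 892 +/- 2*303 Hz
  duration: [0.03, 0.31]   # 0.17 +/- 2*0.07 s
- target_class: POP
  priority: 8
  sound_class: [click]
  contour: any
  harmonic: any
  peak_freq: [300, 3000]   # most energy between 0.3 and 3.0 kHz
- target_class: CR
  priority: 9
  sound_class: [broadband_click]
  contour: any
  harmonic: any
  peak_freq: [100, 8000]   # most energy between 0.1 and 8.0 kHz
- target_class: LFN
  priority: 10
  sound_class: [narrowband_tonal]
  contour: [downsweep]
  harmonic: any
  min_freq: [0, 2000]      # fundamental below 2 kHz
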