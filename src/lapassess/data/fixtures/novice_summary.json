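{
  "frames_assessed": 80,
  "frames_front": 80,
  "frames_paired": 80,
  "frames_skipped": 0,
  "frames_top": 80,
  "hand_skips": {
    "left": 0,
    "right": 0
  },
  "letter_fractions": {
    "A": 0.0,
    "B": 0.5375,
    "C": 0.275,
    "D": 0.1875,
    "E": 0.0
  },
  "mean_fpa": 57.21252445098338,
  "min_fpa": 24.099313677609693,
  "unmatched_front": 0,
  "unmatched_top": 0,
  "warnings": []
}
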