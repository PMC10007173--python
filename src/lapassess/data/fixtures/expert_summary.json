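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
    "A": 0.4125,
    "B": 0.5875,
    "C": 0.0,
    "D": 0.0,
    "E": 0.0
  },
  "mean_fpa": 79.38379523814024,
  "min_fpa": 74.33632964814085,
  "unmatched_front": 0,
  "unmatched_top": 0,
  "warnings": []
}
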