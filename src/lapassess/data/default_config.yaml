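# Default lapassess configuration.
#
# Every number the assessment depends on lives here: camera calibration,
# field-of-interest geometry, membership-function breakpoints, the two rule
# tables, and the stream-fusion policy.  The shipped values reproduce the
# published supervisor: 1280x720 frames at 30 FPS, three 50%-overlapping
# input regions per axis, five letter grades over 0-100%, and the two
# printed 9-rule tables.
#
# Units: _px fields are pixels, _cm fields centimetres, universes are cm for
# inputs and percent for scores.  The frame origin is the top-left corner,
# so on the front camera a SMALLER height coordinate is physically HIGHER.

cameras:
  top:
    frame_width_px: 1280
    frame_height_px: 720
    real_width_cm: 40.0       # physical extent seen by the camera (16:9 kept)
    real_height_cm: 22.5
  front:
    frame_width_px: 1280
    frame_height_px: 720
    real_width_cm: 40.0
    real_height_cm: 22.5

field:
  center_cm: [20.0, 11.25]    # centre of the field of interest, top view
  front_band_cm: [7.5, 15.0]  # acceptable height band, front view

variables:
  distance:                   # first input per hand: distance to field centre
    name: Dis_Cam1
    universe: [0.0, 24.0]     # max reachable distance from the centre ~23 cm
    labels:
      Close:  {shape: triangular, breakpoints: [0.0, 0.0, 12.0]}
      Middle: {shape: triangular, breakpoints: [0.0, 12.0, 24.0]}
      Far:    {shape: triangular, breakpoints: [12.0, 24.0, 24.0]}
  height:                     # second input per hand: front-view height
    name: H_Cam2
    universe: [0.0, 22.5]
    labels:
      High:  {shape: triangular, breakpoints: [0.0, 0.0, 11.25]}
      Field: {shape: triangular, breakpoints: [0.0, 11.25, 22.5]}
      Down:  {shape: triangular, breakpoints: [11.25, 22.5, 22.5]}
  hand_score:                 # first-level output (SRHPA / SLHPA), percent
    # Declared best-first; letter-grade ties fall to the worse label.
    # Edge labels are shouldered so the whole universe is covered.
    name: HPA
    universe: [0.0, 100.0]
    labels:
      A: {shape: trapezoidal, breakpoints: [70.0, 90.0, 100.0, 100.0]}
      B: {shape: triangular,  breakpoints: [50.0, 70.0, 90.0]}
      C: {shape: triangular,  breakpoints: [30.0, 50.0, 70.0]}
      D: {shape: triangular,  breakpoints: [10.0, 30.0, 50.0]}
      E: {shape: trapezoidal, breakpoints: [0.0, 0.0, 10.0, 30.0]}
  refuzzified:                # second-level inputs (SRHPAr / SLHPAr), percent
    name: HPAr
    universe: [0.0, 100.0]
    labels:
      Excellent: {shape: triangular, breakpoints: [50.0, 100.0, 100.0]}
      Good:      {shape: triangular, breakpoints: [0.0, 50.0, 100.0]}
      Bad:       {shape: triangular, breakpoints: [0.0, 0.0, 50.0]}
  final_score:                # second-level output (FPA), percent
    name: FPA
    universe: [0.0, 100.0]
    labels:
      A: {shape: trapezoidal, breakpoints: [70.0, 90.0, 100.0, 100.0]}
      B: {shape: triangular,  breakpoints: [50.0, 70.0, 90.0]}
      C: {shape: triangular,  breakpoints: [30.0, 50.0, 70.0]}
      D: {shape: triangular,  breakpoints: [10.0, 30.0, 50.0]}
      E: {shape: trapezoidal, breakpoints: [0.0, 0.0, 10.0, 30.0]}

rules:
  # First level, identical for both hands: rows are height labels, columns
  # distance labels.
  first_level:
    High:  {Close: B, Middle: E, Far: E}
    Field: {Close: A, Middle: B, Far: C}
    Down:  {Close: B, Middle: B, Far: D}
  # Second level: rows are the RIGHT hand (SRHPAr), columns the LEFT hand
  # (SLHPAr).  The published table is asymmetric (Good x Bad -> E but
  # Bad x Good -> D) and is encoded verbatim.
  second_level:
    Excellent: {Excellent: A, Good: B, Bad: C}
    Good:      {Excellent: B, Good: C, Bad: E}
    Bad:       {Excellent: C, Good: D, Bad: D}
  # Replace both mixed Good/Bad cells with D, the value consistent with the
  # ordering of the rest of the table; restores monotonicity of the final
  # grade in each hand.  Off by default: fidelity first.
  symmetrize_second_level: false

defuzzification: center_of_average   # or center_of_gravity

fusion:
  pairing_tolerance_s: 0.02   # half the 30 FPS frame interval
  min_score: 0.5              # detections below this confidence are dropped
  hold_frames: 15             # top-view dropouts bridged for up to 0.5 s
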