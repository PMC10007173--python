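# Methods

## Measurement model

Each camera is treated as an orthographic view with per-axis scaling: a
frame of `W×H` pixels spans a known physical extent, so
`px_per_cm_w = W / real_width_cm` and `px_per_cm_h = H / real_height_cm`.
There is no lens model, no homography and no stereo triangulation — the
cameras are assumed square-on to the workspace, which is how box trainers
are normally rigged. The instrument tip is proxied by its detection
bounding-box centroid; this overestimates the tip position by roughly half
a box, uniformly, so it cancels out of *relative* judgements (near/far from
the field, high/low above the board).

The two measured quantities per hand and frame are

* `Dis` — Euclidean distance (cm) from the top-view centroid to the centre
  of the field of interest `(x_f, y_f)`;
* `h` — the front-view vertical centroid coordinate (cm). The frame
  origin is the top-left corner, so **smaller `h` is physically higher**;
  the High/Field/Down regions map top-to-bottom on the front frame.

Defaults: 1280×720 px frames at 30 FPS, physical extent 40 × 22.5 cm
(keeps the 16:9 aspect so pixels are square under the default calibration;
anisotropic pixels are supported by the per-axis scaling), field centre at
the frame centre (20, 11.25) cm. The physical extents are not measurable
from detections alone and are deliberately configuration, not constants.

## The fuzzy supervisor

Both cascade levels are classical Mamdani MISO systems: singleton
fuzzification, min-conjunction of rule antecedents, max-aggregation per
output label, centroid defuzzification. The rule bases must tile the full
cross-product of input labels exactly once (9 rules for 3×3 inputs), and
out-of-universe inputs are clamped to the universe bounds; together these
guarantee at least one rule always fires, so defuzzification is total.

Membership functions are triangular or trapezoidal. Input variables use
three 50 %-overlapping labels spanning the universe (shouldered at the
edges): Close/Middle/Far for `Dis` over [0, 24] cm — 24 cm is just above
the farthest reachable corner distance — and High/Field/Down for `h` over
[0, 22.5] cm. Output variables carry five letter grades over [0, 100] %
with interior peaks at 30/50/70 (D/C/B) and shouldered trapezoids
(0, 0, 10, 30) and (70, 90, 100, 100) for E and A. Shouldering the edge
labels keeps the variable complete at the universe endpoints, which a
10-peaked edge triangle would not; the centre-of-average representative
points of E and A are therefore the plateau midpoints 5 and 95. The
second-level input variable (Excellent/Good/Bad over [0, 100] %) is the
three-label analogue.

Two defuzzifiers are provided:

* **center_of_average** (default): activation-weighted mean of the
  activated labels' representative points. This matches the discrete
  weighted-sum centroid formula directly and is cheap enough to run per
  frame.
* **center_of_gravity**: centroid of the max-aggregated, min-clipped
  output surface. Because every surface here is piecewise linear, the
  implementation enumerates all kinks (MF breakpoints, clip crossings,
  pairwise crossings of the clipped segments) and integrates each linear
  segment exactly (Simpson's rule is exact for the quadratic `x·g(x)`),
  so it carries no grid-resolution error. Tests check it against an
  independent 2×10⁵-point brute-force grid centroid to 1e-6 relative.

Letter grading maps a crisp percent back to the label of maximal
membership; exact ties resolve to the worse grade, erring against the
trainee. Output labels are declared best-first in the configuration to
encode that order.

### Rule tables

First level (rows: height label; columns: distance label; identical for
both hands, so the left/right assessment is symmetric by construction):

|       | Close | Middle | Far |
|-------|-------|--------|-----|
| High  | B     | E      | E   |
| Field | A     | B      | C   |
| Down  | B     | B      | D   |

Second level (rows: right hand SRHPAr; columns: left hand SLHPAr):

|           | Excellent | Good | Bad |
|-----------|-----------|------|-----|
| Excellent | A         | B    | C   |
| Good      | B         | C    | E   |
| Bad       | C         | D    | D   |

The second-level table is asymmetric — (Good, Bad) → E but (Bad, Good) →
D — and is encoded verbatim. Whether that asymmetry is intended (e.g.
dominant-hand weighting) or a transcription slip is unknowable from the
table alone, so a configuration switch `symmetrize_second_level` (off by
default) replaces both mixed cells with D, the value consistent with the
ordering of the rest of the table.

### Known limitation: the cascade is not globally monotone

At pure label prototypes the symmetrized table orders the final grade
correctly (Bad < Good < Excellent in either hand). Between prototypes,
however, max-aggregated Mamdani inference with centroid defuzzification is
*not* monotone, regardless of the rule table: improving one hand's crisp
score can raise the activation of a worse-consequent rule (through the
rising mid-label degree) while every better consequent stays capped by the
other hand's degrees, shifting centroid mass downward. Concretely, with
the left hand fixed at crisp 10 %, raising the right hand from 25 % to
40 % lowers the FPA from 35.7 % to 34.0 %. The dips are small (a few
percent) and local, and prototype ordering is unaffected, but a strict
"improving either hand never lowers the final grade" guarantee cannot be
made for this inference scheme; the behaviour is pinned in the test suite
as documented behaviour.

## Missing-detection policy

* Hand visible to the top camera but not the front camera: the instrument
  is between the board and the top camera (typically hiding the front
  lens), so its height is substituted with the **High-label prototype**
  (the peak of the High MF, 0 cm by default) and the frame is flagged.
* Hand missing from the top camera: the last known `Dis` is reused for up
  to `hold_frames` frames (default 15 ≈ 0.5 s at 30 FPS — long enough to
  bridge detector flicker, short enough not to fabricate position during
  a real disappearance), after which the hand is skip-flagged.
* A frame with either hand skipped produces no final grade and is counted
  in the session summary rather than silently dropped; assessed + skipped
  equals the number of paired frames.

## Stream fusion

The two cameras are modelled as independent ordered streams merged
deterministically (a synchronization contract, not a threading
implementation). Pairing is greedy nearest-timestamp within a tolerance
(default 20 ms, half the 30 FPS frame interval); for sorted streams the
two-pointer sweep attains the maximum number of pairs, which the tests
verify against exhaustive bipartite matching. Hand assignment prefers the
detector's right/left class labels (highest confidence per class),
falling back to x-ordering (rightmost centroid = right hand) for
unlabelled graspers; detections under `min_score` (default 0.5) are
dropped. Per-frame processing is constant-memory; only the output series
and scalar aggregates accumulate.

The session aggregate is the arithmetic mean of per-frame FPA plus
per-letter dwell fractions and bookkeeping counts; no published aggregate
formula exists, so the mean was chosen as the least-structured summary of
the time series.

## Synthetic sessions

The generator emulates the *geometry* of trainee behaviour, not its
appearance. Each hand's tip follows a mean-reverting (discrete
Ornstein–Uhlenbeck) walk around a home position near the field centre —
the simplest process with a tunable dwell near a target — switched by a
two-state semi-Markov excursion process: with per-frame probability
`excursion_prob` the hand enters a Far excursion (radial target
`far_offset_cm` from the centre) or a High excursion (height target
`high_height_cm`), each held with geometric dwell of mean
`excursion_dwell_frames`. While the hand is in the High band (where the
High label dominates, below ≈ 5.6 cm by default) the front detection is
dropped with probability `occlusion_prob`. Detection noise comprises
centroid jitter (px), uniform confidence scores and i.i.d. false
negatives; bounding boxes have a nominal 120×60 px size with 10 % jitter,
growing as the instrument nears the top camera. A ground-truth sidecar
records the true per-frame `Dis`, `h`, excursion state and
occlusion/detection flags for oracle tests.

Profile defaults place the expert's hands ≈ 2.7 cm from the field centre
with 0.35 cm jitter and rare excursions (p = 0.005), and the novice's
≈ 8.2 cm away with 1.5 cm jitter and frequent excursions (p = 0.03, mean
dwell 15 frames, stationary excursion occupancy p/(p+q) ≈ 0.31). These
emulate the qualitative behaviours the supervisor is designed to separate:
staying near the field versus drifting Far and lifting High.

What passing synthetic tests does **not** show: robustness to correlated
detector failures, bounding-box aspect changes from instrument pose, rolling
shutter or camera desynchronization beyond a constant drift, and any
appearance-level effect — a real detector's error structure is richer than
centroid jitter plus i.i.d. dropouts.

The packaged fixtures are 80-frame expert and novice sessions (seeds 101
and 202) checked byte-for-byte against regeneration; acceptance-scale
simulations use 600 frames × 20 seeds, sized to estimate letter fractions
and mean-FPA separation stably while keeping the whole suite fast.

## Numerical choices

* Coordinates are continuous; no integer rounding of centroids (the
  generator rounds emitted file values only, for compact fixtures).
* Clamping, not rejection, for out-of-universe fuzzy inputs.
* Exact piecewise-linear integration for center_of_gravity (above);
  degenerate zero-area surfaces raise rather than return NaN.
* Letter ties resolve to the worse grade; region-classification helpers
  share the same later-label-wins rule.
* The completeness validator samples 1001 universe points with the
  endpoint clamped against floating-point round-up.
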