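# lapassess

Autonomous 3D assessment of a trainee's hand movements during laparoscopic
box-trainer exercises (e.g. the FLS peg-transfer task), from dual-camera
instrument detections, using a cascaded Mamdani fuzzy supervisor.

## The problem and the method

During box-trainer practice an expert normally watches the trainee and
judges whether the instrument tips stay near the field of interest and at a
sensible working height. `lapassess` automates that judgement. It consumes
per-frame object-detection records (class label, confidence, bounding box)
from two synchronized cameras:

* the **top camera** gives each grasper tip's in-plane position; its first
  fuzzy input is the Euclidean distance `Dis = √((x_c − x_f)² + (y_c − y_f)²)`
  from the detection centroid to the field-of-interest centre, in cm
  (pixels are scaled per axis by `px_per_cm = frame_px / real_cm`);
* the **front camera** gives the tip's height `h` — the vertical centroid
  coordinate in cm, top-left origin, so smaller `h` means physically
  higher.

Each hand is graded by a two-input Mamdani system: singleton fuzzification
of `(Dis, h)` on the Close/Middle/Far and High/Field/Down regions, nine
IF-THEN rules with min-conjunction and max-aggregation, and centroid
defuzzification

    x* = Σ μ(x_i)·x_i / Σ μ(x_i)

to a percent score with a letter grade A–E (SRHPA for the right hand,
SLHPA for the left). The two crisp scores are then *refuzzified* on a
coarser Excellent/Good/Bad variable and a second-level nine-rule system
cascades them into the final performance assessment (FPA). A hand the
front camera cannot see while the top camera still sees it is inferred to
be in the High region (it is hiding the lens) and graded accordingly.

Everything numeric — calibration, field geometry, membership breakpoints,
rule tables, fusion policy — lives in one YAML document
(`src/lapassess/data/default_config.yaml`).

## Worked example

Simulate a 600-frame novice session and assess it:

```sh
lapassess simulate --profile novice --frames 600 --seed 42 --out-dir scratch
lapassess assess --top scratch/novice_top.jsonl \
                 --front scratch/novice_front.jsonl --out-dir scratch/out
```

which prints

```
assessed 600 frames (0 skipped, 0+0 unmatched); mean FPA 56.7%
wrote scratch/out/series.csv and scratch/out/summary.json
```

`series.csv` holds the per-frame time series (distances, heights, SRHPA,
SLHPA, FPA crisp + letter, flags); `summary.json` the aggregate: the mean
FPA of 56.7 % sits between the C (50) and B (70) grade prototypes — a
middling performance, which is what the novice profile's wide jitter and
frequent Far/High excursions should produce. An expert profile under the
same pipeline scores about 79 % (letter fractions concentrated on A/B).

To see why a single frame got its grade:

```sh
lapassess explain-frame --dis 0 --height 11.25
```

```
inputs: {"Dis_Cam1": 0.0, "H_Cam2": 11.25}
fuzzified Dis_Cam1: Close=1.000, Middle=0.000, Far=0.000
fuzzified H_Cam2: High=0.000, Field=1.000, Down=0.000
rule Field ∧ Close → A (strength 1.000)
activations: A=1.000, B=0.000, C=0.000, D=0.000, E=0.000
crisp: 95.00% → A
```

## Layout

| module | contents |
| --- | --- |
| `lapassess.fuzzy` | membership functions, linguistic variables, rules, Mamdani inference, both defuzzifiers |
| `lapassess.geometry` | bounding boxes, px↔cm calibration, field distance, front-camera height |
| `lapassess.assessment` | the two-level cascade, refuzzification, missing-detection policy |
| `lapassess.streams` | frame pairing, hand assignment, whole-session assessment |
| `lapassess.io` | JSONL/CSV detection streams, results, truth sidecars |
| `lapassess.config` | the validated YAML configuration document |
| `lapassess.simulate` | seeded skill-profile session generator and packaged fixtures |
| `lapassess.cli` | the `lapassess` command |

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
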