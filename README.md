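# hierfusion

Hierarchical fusion of wearable motion-sensor data and egocentric photo
streams for recognizing activities of daily living (ADLs).

## The problem

Chest- or head-worn lifeloggers record two very different streams: a
6-channel IMU (3-axis accelerometer + 3-axis gyroscope, ~90 Hz) and a
timestamped photo stream. Neither modality recognizes everyday activities
well on its own. The IMU separates *motion states* — lying, sedentary,
standing, walking — with high accuracy, but activities that share a motion
state (writing vs. computer use, both sedentary) are indistinguishable
from motion alone. Images can tell those apart, but a flat image
classifier must discriminate among all `n` activities at once, and simply
pooling the two flat softmax outputs ("direct fusion") lets the weak
sensor posterior drag the result down.

`hierfusion` implements the coarse-to-fine alternative. Given an activity
set `A = {A_1..A_n}`, a motion-state set `M = {M_1..M_m}` (`m ≤ n`), and a
many-to-many correspondence `C` assigning each activity to every motion
state it can occur in (its inverse `C⁻¹(M_j)` defines the activity group
of state `j`), recognition proceeds in two stages for every frame shot at
time `t_c`:

1. The sensor segment in the window `[t_c − t_w/2, t_c + t_w/2)` (default
   `t_w = 3 s`) is classified by an LSTM,
   `y = softmax(FC(LSTM(x)))`, and its argmax `j` routes the sample to
   group `C⁻¹(M_j)`.
2. If the group is a singleton, its activity is emitted directly. Otherwise
   a group-restricted image classifier decides within the group: for
   low-frame-rate photo streams a single-frame head
   `y_t = softmax(FC(GAP(conv(I_t))))`, for high-frame-rate streams a
   frame-sequence network `y_t = softmax(FC(LSTM({f_1..f_K})))` over
   per-frame GAP features.

Because the image classifier sees only the routed group's candidates, its
job is easier than flat classification, and the sensor contributes exactly
the information it is good at. The package ships the published hierarchies
(a 15-activity / 4-state chest-logger correspondence and four 20-activity
groupings `M5`–`M8`), the direct-fusion and single-modality baselines, an
evaluation suite (confusion matrices, per-class F1, sequence-level
cross-validation splits), an online-cost model for both architectures, and
a seeded synthetic generator that reproduces the statistical structure the
framework assumes — so every stage is trainable and testable on a laptop
with no external data.

## Worked example

Train and compare all five recognizers on the synthetic chest-logger-like
condition (15 activities, 4 motion states, one frame every 4 s, 5000
samples, fixed seed):

```bash
hierfusion run --preset ebutton-like --n 5000 --seed 13 --outdir runs/demo
```

prints

```json
{
  "sensor_flat":  {"accuracy": 0.247, "macro_f1": 0.159},
  "image_flat":   {"accuracy": 0.680, "macro_f1": 0.674},
  "direct_avg":   {"accuracy": 0.768, "macro_f1": 0.763},
  "direct_max":   {"accuracy": 0.735, "macro_f1": 0.730},
  "hierarchical": {"accuracy": 0.813, "macro_f1": 0.813}
}
```

(values rounded here; the run directory holds full-precision reports,
per-method confusion matrices, and per-sample predictions). Reading the
numbers: the flat sensor-only classifier sits near within-group chance
(macro-F1 0.159) because activities sharing a motion state draw identical
sensor distributions; the flat image classifier reaches 0.674 against all
15 candidates; pooling both posteriors helps (0.763 avg / 0.730 max); the
hierarchical cascade is best at 0.813 — its motion layer routes perfectly
(state accuracy 1.0 in this run, reported under `motion_layer` in
`summary.json`) and each group classifier faces at most 11 candidates
instead of 15. This is the asymmetric-separability regime in which routing
beats pooling.

The online cost model compares both architectures per frame:

```bash
hierfusion cost-model --t-of 12.2 --t-c1 9.709 --t-l1 0.659 \
                      --t-c2 2.395 --t-l2 0.659 --t-cl 4.103
```

gives `t1 ∈ [53.527, 56.163]` ms for the direct-fusion baseline (dominated
by optical-flow extraction) versus `t2 ∈ [2.395, 4.762]` ms for the
hierarchical pipeline — raw sustainable frame rates of roughly 18–19 fps
versus 210–418 fps.

Other subcommands: `generate`, `align`, `train-motion`, `train-groups`,
`recognize`, `evaluate`, `sweep` (grouping-granularity sweep over
`M5`–`M8`). Everything is also available as a library; see
`docs/methods.md` for the model and design notes.

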