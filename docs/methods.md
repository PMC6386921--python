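# Methods and design notes

This note documents the models implemented in `hierfusion`, the synthetic
study conditions, and the design choices made where more than one
reasonable option existed. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The recognition model

**Label structure.** Recognition is defined over an ordered activity set
`A` (size `n`) and an ordered motion-state set `M` (size `m ≤ n`), linked
by a correspondence `C ⊆ A × M`: activity `a` is linked to every motion
state it can occur in. The inverse image `C⁻¹(M_j)` is the *group* of
state `j`. When every activity has exactly one state, `C` is a function
and the groups partition `A` (group sizes sum to exactly `n`); any
multi-state activity makes the groups overlap (sizes sum to more than
`n`). Both label sets are ordered, and the activity order is canonical: a
group is always reported in activity order, and group-local classifier
outputs map back to global indices through it. Validation is strict — an
activity outside every group can never be emitted by the cascade, so
coverage failure is a construction error, not a warning.

**Windows and alignment.** Each photo-stream frame shot at `t_c` owns the
sensor window `[t_c − t_w/2, t_c + t_w/2)` with `t_w = 3 s` by default.
Windows are half-open so adjacent non-overlapping windows partition time
(endpoint handling is not prescribed anywhere authoritative; this is our
convention). A window is materialized as a fixed-length `L × 6` segment
with `L = round(fs · t_w)` (`L = 270` at 90 Hz): rows are selected by
nearest-sample-index arithmetic from the nominal rate rather than
per-sample timestamp search (deterministic, jitter-free), and rows outside
the recording are filled by edge replication and flagged. Continuous
streams are segmented with window centers at `(k + ½)·Δc`,
`k = 0..⌊D/Δc⌋−1`; this is the unique uniform-spacing convention that
yields 15 windows from a 15 s recording at `Δc = 1 s`, and boundary
windows get full `t_w` support through the clipping+padding rule above.

**Classifiers.** Three contracts:

* *Motion-state classifier*: single LSTM layer (default 128 hidden units)
  over the standardized segment, fully connected layer to `m` logits,
  softmax. Its argmax routes the sample.
* *Group frame classifier* (low frame rate): a frozen feature extractor
  producing spatial feature maps, global average pooling (GAP: one spatial
  mean per map), and a fine-tuned fully connected softmax head over the
  group's `n_j` activities.
* *Group frame-sequence classifier* (high frame rate): per-frame GAP
  features through an LSTM (default 512 hidden units), a 512-unit fully
  connected layer with dropout 0.7, and a softmax head. `K = 1` degenerates
  to single-frame classification through one recurrent step.

Training defaults are the published settings: Adam with learning rate
0.001 and moment decays 0.9 / 0.99; 150 epochs, batch 30 for the motion
net; 50 epochs, batch 8 for image heads. The motion classifier uses no
dropout (the published configuration applies dropout only to the
image-sequence networks; we preserve that asymmetry). No class weighting
or softmax temperature is applied anywhere. Sensor segments are
standardized per channel with training-set statistics (a choice of ours;
nothing authoritative prescribes normalization). Weight initialization is
seeded: Glorot-uniform input weights, orthogonal recurrent blocks, +1
forget-gate bias, and zero-initialized output heads — so an untrained head
emits exactly uniform probabilities, and training is bit-reproducible from
the config seed on a single-threaded BLAS.

**The neural core.** No deep-learning framework is used: the package
contains a compact numpy implementation (`hierfusion._nn`) of exactly the
pieces the contracts need — LSTM with full backpropagation through time,
dense layers, inverted dropout, softmax cross-entropy, Adam. Gradients are
verified against central finite differences in the test suite.

**Feature extraction.** The extractor is an injectable contract
(image → stack of spatial maps). Three implementations ship: a
pass-through for precomputed feature vectors (viewed as `d` maps of size
1×1, making GAP the identity — the default for synthetic data); a small
seeded convolutional stack (two 3×3 stride-2 conv+ReLU stages) whose
filters are drawn once and never trained, acting as a deterministic
random-projection feature bank for raster input; and the option to drop in
an externally pretrained backbone by replacing the parameters wholesale.
Every training routine freezes the extractor and fine-tunes heads only —
the frozen contract is asserted by parameter checksum — so no gradient
path into the extractor exists, and none is offered.

**Fusion.** The cascade uses hard routing (argmax of the motion
posterior), exactly as the two-stage algorithm prescribes; soft mixing
over groups is a non-goal. Samples routed to singleton groups bypass the
image path entirely. All argmax ties break toward the lowest canonical
index (our rule; the degenerate exactly-uniform posterior is not otherwise
specified). A prediction is scored correct iff the final activity label
matches the ground truth, regardless of which of a multi-state activity's
groups it was routed through. The direct-fusion baseline pools flat
per-modality softmax vectors elementwise: average pooling preserves the
simplex; maximum pooling is renormalized for posterior reporting only (the
argmax is unaffected by renormalization). During group-bank training, a
multi-state activity contributes its samples to every group it belongs to.

**Evaluation.** Per-class precision, recall and F1 are computed
one-vs-rest from the confusion matrix, with `0/0 → 0` for absent classes;
the headline figure is the unweighted (macro) mean of per-class values,
matching how the published per-group averages are formed. The
cross-validation protocol for sequence corpora builds `k` splits whose
test sides hold exactly one sequence per activity (seeded assignment).
When an activity has more than `k` sequences the surplus stays in every
training split; the test splits partition the corpus exactly when every
activity has exactly `k` sequences (the reference case is 20 activities ×
10 sequences, `k = 10`).

**Online cost model.** The per-frame cost of the direct-fusion baseline is
bounded by `2·t_OF + 3·t_C1 ≤ t1 ≤ 4·t_L1 + 2·t_OF + 3·t_C1` (two optical
flow extractions, three conv-net passes, up to four recurrent passes) and
the hierarchical pipeline by `t_C2 ≤ t2 ≤ t_L2 + t_CL`. All constants are
inputs in milliseconds; the module never times this implementation
(hardware-dependent timings are out of scope). Frame rates are returned as
raw floats `1000/t`: the published integer rates cannot all be reproduced
by any single rounding convention (1000/2.395 = 417.5 and 1000/4.762 =
210.0 print as 418 and 209), so the raw values are authoritative and
rounding is left to the caller.

## Synthetic study conditions

The generator encodes the framework's two premises as a known generative
model:

* **Sensor side.** Each motion state owns a 6-channel signal model:
  accelerometer mean = a gravity vector (9.81 m/s² along a state-specific
  unit orientation, placed on a cone around vertical at equally spaced
  angles so states are pairwise separated), plus i.i.d. Gaussian noise
  (SD 0.3 m/s² acc, 0.1 rad/s gyro), plus — for ambulatory states — a
  sinusoidal gait oscillation (amplitude 3 m/s², frequency 1.6 Hz + 0.4 Hz
  per ambulatory state, uniform random phase per segment) along the
  gravity direction, with a matching gyroscope oscillation. Crucially,
  activities sharing a state draw from that state's model *identically*:
  within a group, the sensor carries no activity information by
  construction (verified distributionally by two-sample KS tests in the
  suite).
* **Image side.** Each activity owns a Gaussian feature cluster in `d = 8`
  dimensions: mean drawn once from `N(0, δ²I)` per world seed
  (`δ = separation`, default 1.0), within-cluster SD 1. Low-frame-rate
  payloads are single draws; high-frame-rate payloads are stationary AR(1)
  sequences (`ρ = 0.95`, `K = 90` frames ≈ 3 s at 30 fps) with the
  cluster as marginal — temporally correlated, so a sequence carries more
  information than one frame but much less than `K` independent frames.

The defaults define the two packaged study conditions. `ebutton-like`:
15 activities / 4 states (the chest-logger correspondence), 90 Hz,
`t_w = 3 s`, one frame per window, frames ≥ 4 s apart (disjoint windows).
`multimodal-like` (and `multimodal-m5..m8` selecting the grouping):
20 activities, high-rate regime, 15 s sequences cut into overlapping
windows at 1 s spacing. Separation 1.0 was chosen as the *asymmetric*
regime — motion states essentially perfectly separable while flat image
classification is only moderately accurate — because that is the regime
the hierarchical architecture targets; all accuracy assertions in the
suite are made at these generator-controlled effect sizes, anchored by the
exact Bayes posterior (`bayes_oracle`), which is computable in closed form
up to a numerically marginalized oscillation phase (24-point grid) and an
exact AR(1) likelihood.

What the generator does **not** emulate: real IMU nonstationarity (posture
drift, device re-positioning, magnetometer effects), image content
(payloads are feature vectors or random rasters, not photographs),
class imbalance (proportions are uniform by default, configurable),
camera/IMU clock drift, and label noise. Passing tests therefore
demonstrate the correctness and internal consistency of the machinery and
the direction of the architectural effects under the assumed structure —
not performance on real lifelogging data.

## Problem sizes and numerical choices

Desk-scale reduced training profiles ship alongside the published
defaults and are used by the test and demonstration runs: motion nets with
32 hidden units, 8 epochs, batch 64, time-axis stride 3 (90 of 270
samples), learning rate 3e-3; frame heads with 30 epochs, batch 32;
sequence nets with 48 hidden units, 12 epochs, stride 3, dropout 0.3. The
end-to-end comparison runs on 5000 samples (70/30 split); the premise
checks on 3000; the grouping sweep on 400 samples per grouping. These
sizes were chosen so the whole suite runs in minutes on one CPU while
leaving the tested effects far from their decision thresholds.

Numerical details: probability outputs are exact simplices to 1e-6
(softmax with max-subtraction); sigmoid arguments are clipped at ±50;
normalization SDs are floored at 1e-8; segment extraction tolerates
1e-9 s of floating-point slack in the window count. Degenerate inputs have
defined behavior throughout: single-class training data, singleton-group
image training, empty frame sequences, windows fully outside the
recording, and inverted cost intervals all raise informative errors; the
`m = 1` hierarchy needs no motion model and reduces the cascade to flat
image classification.

## Known limitations

* The pure-numpy trainer is single-threaded and unsuitable for
  ImageNet-scale backbones; the extractor contract exists precisely so a
  pretrained backbone can be adapted in without touching the cascade.
* Hard routing means a motion-layer error is unrecoverable for activities
  absent from the routed group; the sweep quantifies this coupling but no
  soft-routing fallback is provided (by design).
* The frame-sequence classifier is order-sensitive by construction; for
  constant inputs its prediction is order-invariant but not invariant to
  sequence length `K` (the recurrent state approaches its fixed point with
  `K`), which is inherent to the architecture.
* Grouping design is manual: the package validates and evaluates a given
  correspondence but does not learn one from data.
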