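# Methods

## Problem and scope

The task is temporal segmentation of laparoscopic cholecystectomy video:
assign one of seven workflow phases to every second of a procedure. The
package implements the full two-stage recipe — short-term clip
classification followed by long-term recurrent smoothing — together with
the task's evaluation metrics and the experiment protocols (data-size
sweep, generalization breakdowns, new-center adaptation). Because the
video corpora for this task are restricted, all end-to-end behaviour is
exercised on synthetic phase-sequence data; the clip-level path runs on
rendered synthetic frames. Pre-training the full-scale inflated ResNet-50
backbone and reproducing real-data headline accuracies are out of scope.

## Phase ontology and time base

Seven phases, ids 0–6: Preparation, Adhesiolysis, Dissection, Division,
Separation, Packaging, Final inspection. Adhesiolysis and Packaging are
optional; Packaging may follow Final inspection; Dissection/Division may
alternate. Time is 1-second resolution, 0-based; segments are half-open
`[start_s, end_s)` so a segmentation partitions `[0, L)` exactly and the
run-length encoding of a track is invertible. Annotation files are CSV
(`video_id,second,phase_id`, dense seconds) or JSON run-length segments;
no standard format exists for per-second surgical phase labels, so the
format is the package's own.

## Short-term model contract

- **Clip geometry.** 2.56 s at 25 FPS = 64 frames. "Around that second"
  is resolved as a window centred on the anchor frame (32 before, 31
  after), clamped by edge-frame repetition at video boundaries so the
  length is invariant. During training the anchor frame is uniform over
  the 25 frames of the second; at evaluation it is fixed to frame 12
  (middle of the second).
- **Preprocessing.** Short side resized to 256 px (bilinear), 224×224
  crop (random in training, centred at evaluation), per-channel
  standardization with the ImageNet statistics. Desk-scale runs pass
  smaller sizes through the same code path.
- **SDR.** `second / video_length` in [0, 1), concatenated to the pooled
  feature vector immediately before the linear classification head — the
  most literal reading of injecting it "before the classification
  layer". The trimmed video length is used, since all training follows
  trimming.
- **Schedule.** SGD, lr 0.01, momentum 0.9, 16 clips per batch sampled
  by (random video, random second); validation every 250 000 samples
  (every epoch when the pool is smaller); lr ÷10 after validation
  iterations 10, 20, 25; stop at 30. This implies 2.5 M / 5 M / 6.25 M /
  7.5 M samples at the drop and stop points — asserted analytically in
  the tests.
- **Backbone.** The full-scale specification (ImageNet-initialized
  ResNet-50 inflated to 3D with non-local blocks, Kinetics pre-training)
  is recorded in `BackboneSpec` but not instantiable here. The default
  backbone is a ~5-layer 3D conv net: two non-overlapping space-time
  patch convolutions (3→16→32 channels) with ReLU, global average
  pooling, optional SDR concatenation, linear 7-way head. Non-overlapping
  patches keep the backward pass a pure reshape, which is what makes
  CPU-scale training fast.
- **Trimming.** Out-of-body detection is a pluggable per-second frame
  classifier; the default heuristic marks red-dominant, mid-brightness
  frames as in-body, and the trim keeps the longest contiguous in-body
  run.

## Long-term model

Input is a per-second phase-id sequence. Training augmentation: soften
each probability row with temperature T = 11 (`q ∝ p^(1/T)`, the
distillation form restricted to the simplex — identity at T = 1,
order-preserving for all T > 0; zero entries floored at 1e-12), then draw
one phase per second from the softened categorical, freshly per epoch.
The id sequence is embedded (dim 32), processed by one bidirectional LSTM
layer with 128 hidden-state features per direction, and mapped to 7
logits per second. Per-second cross-entropy, SGD with fixed lr 0.1 and
momentum 0.9, one video per step (sequences differ in length), 30 epochs.

Inference is deterministic: the argmax ids of the input rows pass through
the network once, no temperature or sampling (an alternative that
averages logits over k sampled sequences is provided). A no-augmentation
training mode (argmax inputs) exists for ablation. The embedding-lookup
design means the network consumes hard ids only; soft probability input
is deliberately not implemented.

Numerical choices: gates are computed in one fused matmul per step;
parameters are initialized uniform(−1/√H, 1/√H) (embedding N(0,1));
gradients are clipped to global norm 5 before each update, a stabilizer
for fixed-lr-0.1 training on short sequences; momentum buffers start at
zero, including when fine-tuning from a baseline. Argmax ties break to
the lowest phase id everywhere.

## Synthetic data

The generator produces what the downstream stages consume, under
explicit study conditions:

- **Truth tracks.** Base order 0→…→6 with independent skips
  (P(skip Preparation)=0.1, Adhesiolysis=0.5, Packaging=0.15 — the
  Adhesiolysis default reflects that division of adhesions happens only
  when adhesions exist), a Dissection↔Division alternation inserted
  after Division with probability 0.2, and Packaging deferred past Final
  inspection with probability 0.1. Phases 2, 3, 4, 6 are always present.
  Durations are log-normal per phase (method-of-moments from mean/sd),
  defaults summing to ~43 min procedures with Dissection and Separation
  dominating. Desk-scale runs use `config.scaled(f)`, which multiplies
  all durations by `f` but leaves the structure untouched.
- **Emissions.** Per-second probability rows mimic a trained clip
  classifier's output with its three error types: (1) each transition is
  shifted by a Gaussian offset (sd 3 s, mean 0 by default — a nonzero
  mean models a systematic temporal bias); (2) 20% of the central mass
  leaks to the adjacent phase ids; (3) with rate 0.03 a second is centred
  on a distant phase, drawn near the current progress ratio when SDR
  attenuation is on (a Gaussian kernel of width 0.15 on the progress
  axis), uniformly otherwise. Rows are Dirichlet draws (concentration 15
  times the mean vector, floor 0.02) raised to an overconfidence exponent
  of 8 and renormalized. The exponent matters: Dirichlet rows are roughly
  calibrated, while real softmax outputs of deep networks are sharply
  overconfident, with log-probability margins of tens of nats. Because the
  transform is monotone per row, argmax accuracy is unchanged (~0.85 under
  the defaults, matching a trained clip classifier's level), but
  temperature sampling divides log-probabilities by T, so T = 11 is only
  meaningful relative to this sharpness: with calibrated rows the sampled
  sequences are ~18% correct and augmentation destroys the signal; with
  the realistic sharpness they are ~50–60% correct, which is the regime
  the augmentation is designed for.
- **Metadata.** Centers and surgeons are assigned round-robin with 10%
  random reassignment, or by explicit multinomial weights (used to
  emulate corpora skewed toward one large center).
- **Frames.** `render_phase_frames` produces low-resolution frames whose
  color encodes the phase plus pixel noise — an explicitly crude
  synthetic stand-in that makes the clip path trainable, not an attempt
  at surgical imagery.

What passing tests on this data do **not** show: that the backbone
architecture extracts phase information from real endoscopic imagery,
that the noise structure of a real clip classifier matches the emission
model, or that real-data accuracies are attained. They do show that the
sequence-modeling machinery, metrics and protocols behave as designed
under controlled, realistic error structure.

## Evaluation metrics

Per-second accuracy (= trace/total of the 7×7 truth-by-prediction
confusion matrix; also the support-weighted mean of per-phase recalls —
both identities are asserted exhaustively on small tracks). Mean phase
accuracy averages recalls only over phases present in the truth (recall
over empty support is undefined). Transition accuracy compares, per
phase present in truth, the start of its first truth segment with the
start of its first predicted segment (first-segment convention because
phases can recur); a phase absent from the prediction counts as a miss
at every τ — dropping it would inflate the metric. The default τ grid is
±15…±360 s. Instances are pooled across videos by default (per-video
macro-averaging available). Percentile subsets keep videos strictly
above the given accuracy percentile (linear interpolation of order
statistics). Group breakdowns report boxplot statistics (median,
quartiles, 1.5·IQR whiskers, outliers beyond) for groups with more than
`min_n` videos (default 10).

## Experiment protocols

- **Split.** Test = nearest integer (half-up) to 25% of N; train =
  floor(0.8 · remainder); validation = rest. This convention reproduces
  745/187/311 for N = 1243. Splits are at the video level.
- **Sweep.** Training subsets are nested prefixes of one fixed shuffled
  order, so the size effect is not confounded by resampling; validation
  and test sets are fixed across sizes; hyperparameters fixed.
- **Adaptation.** A baseline smoother is trained for 15 epochs without
  one center, then training continues from its weights on nested subsets
  of new-center videos; evaluation is always on new-center videos never
  used for adaptation. The 5/10/13 lr-drop schedule in `FinetuneConfig`
  belongs to the short-term path; the smoother trains at its fixed rate.
  The synthetic shifted center differs structurally (Packaging deferred
  in 70% of cases, Adhesiolysis rarely recorded, Preparation often
  missing) and systematically (transitions emitted ~4% of the video
  length late, heavier jitter, no SDR attenuation) — learnable shifts,
  which is what gives adaptation headroom beyond irreducible noise.

## Problem sizes

Tests and the acceptance script run the pipeline at desk scale, chosen
as the package's working conditions: tracks scaled to ~2 min
(`scaled(0.05)`, or 0.04 for the multi-seed protocols), 40 training / 30
held-out videos for pipeline runs, sweep sizes 5/20/80 from a pool of
134 videos at 8 epochs over 5 seeds, and adaptation sizes 5/10/20 from a
30-video shifted center over 3 seeds. Multi-seed protocols compare
seed-mean accuracies within one seed-sd of the paired differences.

## Known limitations

- The smoother's zero-shot transfer is strong: its learned behaviour is
  dominated by local denoising, so purely stochastic noise shifts give
  fine-tuning little headroom; the adaptation experiment relies on the
  learnable (structural and systematic) components of the shift.
- On very short scaled tracks, one-second boundary wobble is a visibly
  larger accuracy cost than on full-length procedures; metrics at
  different duration scales are not directly comparable.
- True per-phase duration distributions of real corpora are unpublished;
  the log-normal defaults are the package's own choice, exposed in
  `SimulationConfig`.
- Both models operate offline on the whole video; causal variants are
  deliberately not implemented.
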