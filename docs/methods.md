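# Methods

`fallgcn` classifies short windows of multi-IMU recordings into five fall
types and six activities of daily living (ADLs) with a spatial-temporal
graph convolutional network (ST-GCN) over a body-skeleton graph of the
sensor placements. This note records the model, the protocol, the synthetic
data it is validated on, and the design choices that were genuinely open.

## The skeleton graph and neighbourhood partitions

Five sensors — left ankle (S1), right trouser pocket (S2), waist (S3), neck
(S4), left wrist (S5) — form the nodes of an undirected graph G(V, E). The
sensor layout is known only as a picture of the body, so the edge set is a
modelling choice: the default follows the anatomical chain through the
trunk, S1–S2–S3–S4–S5 (ankle to thigh to waist to neck to wrist), which
respects limb adjacency and keeps the graph connected with the minimum
number of edges. The graph ships as a YAML file and is user-overridable; an
alternative wiring (say, a direct wrist–waist edge) needs no code change.

Spatial graph convolution needs a rule that splits each node's
hop-neighbourhood into K subsets, each with its own weight map
(`W_k`): the kernel of the convolution is

    out = Σ_k (X A_k) W_k ,

applied per frame, where `A_k` is the indicator matrix of subset k after
degree normalization. Three standard partition rules are implemented:

- **uni-labeling** — all neighbours in one subset; K = 1;
- **distance** — label = hop distance from the root; K = MD + 1, where MD
  is the neighbourhood radius in hops;
- **spatial configuration** — compare the neighbour's hop distance to the
  skeleton's gravity centre with the root's own distance: equal → *root*,
  smaller → *centripetal*, larger → *centrifugal*; K = 3 for any MD.

Because the graph carries no coordinates, the "centre of gravity" is the
waist node, the usual convention for skeleton GCNs; it is configurable.
Self-pairs (hop 0) always belong to the neighbourhood. Under spatial
configuration with MD = 2 the 2-hop shell is labelled by the same
centripetal/centrifugal comparison rather than adding shells, so K stays 3
and MD varies independently of the strategy.

Normalization is symmetric per subset, `D_k^{-1/2} R_k D_k^{-1/2}` with
`D_k[i,i] = Σ_j R_k[i,j] + α` and α = 1e-3, which keeps rows with no
support finite (and zero). With α = 0 the familiar textbook matrices are
recovered; the tiny offset only matters for empty rows and perturbs
populated entries by less than 0.1%.

## The classifier

Input windows are tensors (samples × 6 channels × frames × 5 nodes): three
accelerometer axes in g and three gyroscope axes in deg/s per node,
z-scored per channel with statistics from the training split only (a
per-channel, node-independent scheme so that normalization commutes with
node relabelling).

Five residual blocks, each with 32 output channels, apply in order: the
partitioned spatial graph convolution, batch normalization, ReLU, a 1-D
temporal convolution along frames (stride 1, symmetric zero padding),
batch normalization, dropout; the block input re-enters through a residual
connection (a 1×1 channel projection on the first block, identity
afterwards) before a final ReLU. Global average pooling over frames and
nodes yields one 32-vector per window, and a linear softmax head produces
the class probabilities.

Choices the architecture description leaves open, and what this package
does:

- **Temporal kernel: 5 frames (~0.28 s at 18 Hz), odd, configurable.** The
  reference skeleton ST-GCN uses 9 frames at video rate (30 fps ≈ 0.3 s);
  at 18 Hz, 5 frames matches that receptive field in *seconds*, and the
  five-block stack still covers more than one second. It is also ~40%
  cheaper in the dominant GEMM.
- **Layer order** (BN after each convolution, residual around the whole
  block, dropout last before the sum) follows the reference architecture;
  the block is described as a set of components without an order.
- **Dropout 0.5**, inverted scaling, active only in training.
- **Initialization**: variance-scaled (He) uniform for convolution maps,
  Glorot for the projection and head, BN scale 1 / shift 0; all randomness
  flows from one seed.
- **No edge-importance mask** (present in some skeleton GCNs, unstated
  here); exposed as future work rather than a flag that is never exercised.

The network is implemented directly on NumPy arrays with hand-derived
analytic gradients for every layer and a hand-rolled Adam optimizer.
Features are held channels-last internally so that both convolutions
collapse into single BLAS GEMM calls (the spatial convolution contracts a
fused kernel `M[(m,c),(n,o)] = Σ_k A_k[m,n] W_k[c,o]`; the temporal
convolution uses an im2col layout); the memory-bound elementwise chains
(batch norm, dropout + residual + ReLU, im2col gather/scatter) are fused
numba kernels. Correctness is guarded by finite-difference gradient checks
(agreement to ~1e-7 relative in float64) and by brute-force convolution
oracles in the test suite.

## Training and evaluation protocol

- Adam, learning rate 1e-4, minibatch 128, cross-entropy loss.
- Windows are split 80/10/10 (train/validation/test), stratified by label
  with a largest-remainder allocation so the global sizes land within one
  sample of the fractions and every class appears in every split.
- Validation loss is evaluated once per epoch; training stops after
  `patience` evaluations without improvement (default 50) or at
  `max_epochs` (default 1000), and the parameters with the best validation
  loss are returned. A patience denominated in *minibatches* would make the
  validation set the de-facto training signal at batch size 128, so the
  epoch is the patience unit here; a minibatch-level mode is a
  one-line change (evaluate inside the batch loop).
- Repeated ("Monte-Carlo") cross-validation: ten independent random
  80/10/10 partitions with seeds derived from a base seed, reporting
  per-round metrics and their mean ± sd. This matches a protocol of
  "different random partitions"; a classical k-fold split is not provided
  because the random-partition reading is the one the evaluation uses.
- The hyperparameter grid crosses the three partition strategies with
  MD ∈ {1, 2} under identical splits and seeds (six cells); the window
  sweep repeats the pipeline for 1, 2 and 3 s windows at 50% overlap.
- Splitting is by window, not by subject; subject-wise splitting is the
  honest protocol for deployment claims but is deliberately out of the
  default path since the evaluation it mirrors splits by sample. The trial
  metadata carries subject ids, so a subject-wise split is a filter away.

Metrics: confusion matrix (rows = truth), per-class one-vs-rest
TP/FP/FN/TN, accuracy = trace/total, precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 = 2PR/(P+R), all in percent; headline values are **macro**
averages (unweighted over classes), the informative summary under the
heavy ADL/fall imbalance. A diagnostic `precision_formula="literal-eq2"`
computes TN/(TN+FP) — specificity — for comparison with sources that print
that formula under the name "precision"; it is not used in any headline
number because composing it with recall breaks the F1 definition.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *layout* and *signal structure* of a
five-sensor fall/ADL collection: 17 subjects × 11 activities × 3 trials at
18 Hz, with durations of 10 s per fall trial and 60 s (walking, standing,
sitting, lying), 30 s (jumping) and 10 s (picking up an object) for ADLs.

Falls are three-phase: an upright lead-in with loss-of-balance sway
(0.10 g, 0.6 Hz — noticeably above quiet-standing sway), a ~0.4 s
free-fall during which acceleration magnitude ramps to ~0.15 g, a 3.2–6 g
impact spike whose per-node weighting peaks at the sensor nearest the
impact side (wrist for a forward fall onto the hands, ankle/thigh for a
knee fall, waist/neck for a backward fall, ...), and a rest phase with
gravity reoriented to a fall-type-specific lying attitude plus a decaying
tremor; the gyroscope carries a 180–300 deg/s rotation burst about a
fall-type-specific axis. ADLs are periodic (walking at ~1.8 Hz with an
extremity-dominant amplitude gradient; jumping at ~1 Hz with flight dips
and landing spikes), static (standing; lying with gravity rotated to the
horizontal), or single-transition (sitting: one smooth trunk/thigh
reorientation; picking up an object: a ~6 s bend–hold–return trunk pitch
excursion with a wrist reach). Per-subject amplitude/frequency jitter is
±15%, sensor noise defaults to 0.05 g / 5 deg/s, and every trial has its
own random stream keyed on (seed, subject, activity, trial), so the full
dataset is byte-reproducible and any subset regenerable.

Frame labels carry the trial's activity id throughout, so windows cut from
the ambient portions of fall and pick-up trials are intrinsically
ambiguous with standing — the same ambiguity real trial-labelled
collections have. Window labels are the majority frame label with an
earliest-occurrence tie-break and a configurable minimum-fraction floor
below which a window is labelled background (excluded from training by
default).

What the recipes do **not** model: fall biomechanics (no rigid-body
dynamics, no realistic jerk profiles), soft-tissue/mounting artefacts,
sensor drift or dropout, magnetometer effects, inter-activity transitions
inside a trial, or subject-specific movement styles beyond scalar jitter.
Passing the synthetic benchmark therefore demonstrates that the pipeline
learns phase events, orientation changes and periodicity from multi-node
IMU tensors — not that it would reach the same numbers on real recordings.

## Problem sizes and numerical choices

The default end-to-end benchmark segments the 561 synthetic trials into
16,269 two-second windows (36 frames) and trains with a 30-epoch budget —
enough, at learning rate 1e-4, for the benchmark's accuracy to clear 95%
with validation loss still slowly falling; the full-scale budget
(1000 epochs, patience 50) remains the default of `TrainConfig` and of the
CLI. The grid-search and window-sweep harnesses run at 3 subjects and 2
epochs in the test suite and acceptance script: at that scale the cell
values are noisy and only the harness contract (all cells filled, tables
well-formed) is asserted.

Numerical details: float32 parameters and activations (float64 only for
gradient checks and BN statistics accumulation); BN eps 1e-5, running-stat
momentum 0.1; softmax computed with max subtraction; cross-entropy clipped
at 1e-12; a non-finite training loss aborts with a diagnostic. Ties in the
window-label vote go to the earliest label; degree-normalization keeps
empty adjacency rows at zero; zero-variance channels get unit sd in the
z-scoring. Determinism: one integer seed fixes dataset, splits, parameter
initialization, batch order and dropout masks; repeated runs on the same
machine are bit-identical.

## Known limitations

- The NumPy/numba implementation is single-core and roughly an order of
  magnitude slower than a GPU framework; the full 1000-epoch protocol on
  the full dataset is an overnight CPU job.
- Real-data ingestion expects consolidated per-frame CSV with a column
  mapping file; it has been exercised against the package's own export
  format, not against every export dialect of public datasets.
- Macro metrics treat a class absent from a test split as zero
  precision/recall (flagged in the per-class table), which deflates macro
  averages on very small runs.
- The synthetic benchmark's accuracy ceiling is set by the deliberate
  ambient-window ambiguity described above, not by sensor noise.
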