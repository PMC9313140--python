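# Methods

## Problem and pipeline

`pockethar` studies how the window length fed to a hybrid 1D-CNN-LSTM
classifier affects human activity recognition (HAR) from a single
triaxial accelerometer in a pocket-worn smartphone. Six activity classes
are considered: lying, sitting, walking, and treadmill running at 3, 5
and 7 METs (metabolic equivalents of task, oxygen consumption over the
resting rate of 3.5 mL/kg/min).

The pipeline is: simulate (or load) per-participant labeled streams →
resample to a uniform 30 Hz and impute gaps → compute nine
orientation-invariant heuristic features per sample → rank features by
tree impurity and keep the top four → cut stride-1 windows of length W,
each labeled by its last sample → train the 1D-CNN-LSTM → evaluate
leave-one-subject-out (LOSO) over a grid of W.

Because the kind of raw cohort this analysis targets is typically not
redistributable, the package ships a first-class synthetic cohort
generator whose defaults encode the laboratory protocol the analysis
assumes, and the whole pipeline is validated on that synthetic cohort.

## Synthetic cohort generator

Each participant performs the fixed 9-trial, 65-minute schedule
(lying 5′, sitting 5′, walking 10′, lying 5′, run-3MET 10′, lying 5′,
run-5MET 10′, sitting 5′, run-7MET 10′). The generator emulates:

* **Arbitrary fixed device orientation.** Each participant receives a
  uniformly random proper rotation (normalized random quaternion via
  `scipy.spatial.transform.Rotation`); every body-frame sample is mapped
  through it. This is the nuisance the features must cancel.
* **MET-graded signatures.** The body-frame signal is gravity
  (9.81 m/s², SI, gravity-inclusive) along a posture-specific direction
  plus a two-harmonic oscillation of the gait fundamental. Amplitude and
  fundamental grow monotonically with intensity: walking 1.2 m/s² at
  ≈1.8 Hz; running 2.0/3.0/4.0 m/s² at ≈2.2/2.6/3.0 Hz. Lying is pure
  gravity plus sensor noise; sitting adds a small 0.15 m/s² postural
  sway at 0.5 Hz on a tilted gravity direction. Under rotation-invariant
  features the two postures are therefore distinguishable only through
  signal statistics, which reproduces the empirical finding that sitting
  is by far the hardest class. Per-participant factors (gait frequency
  U(1.7, 1.9) Hz, amplitude scale U(0.9, 1.1)) create inter-subject
  variation without making adjacent intensity levels overlap.
* **Irregular sampling.** Piecewise-constant rate in 10-second blocks,
  each block's rate uniform on [5, 19] Hz (a throttling recorder).
  Timestamps are integer milliseconds for unambiguous CSV round-trips.
* **Missing data.** Short contiguous spans (geometric length, mean 4
  samples) of accelerometer rows are set missing until a target
  fraction (default 5%) is reached, mimicking momentary connection loss.
* **Sensor noise.** White Gaussian, default SD 0.1 m/s² per axis.

What the generator does **not** model: biomechanical structure (stride
length, cadence, impact transients), gyroscope/magnetometer channels,
within-trial posture changes, drift, or device-dependent calibration
error. Passing tests on this cohort therefore demonstrate that the
pipeline recovers labels whose generative signatures differ in
amplitude, frequency and statistics under arbitrary rotation and messy
sampling — not that the specific accuracy numbers transfer to real
recordings.

## Preprocessing

Each contiguous activity trial is resampled independently onto a uniform
grid spanning its first to last timestamp (default 30 Hz) by per-axis
linear interpolation through the observed samples; interior gaps are
thereby linearly imputed and leading/trailing gaps take the nearest
observed value. Interpolation never crosses a trial boundary, so no
sample blends two activities. Labels transfer as constants within a
trial (equivalently, nearest-neighbour in time). Resampling an
already-uniform recording at its own rate is the identity on the shared
grid.

## Heuristic features

For samples v_n ∈ R³, with Δv_n = v_{n+1} − v_n and
Δ²v_n = v_{n+2} − 2v_{n+1} + v_n:

* w1–w3: norms of v_n, Δv_n, Δ²v_n;
* w4–w6: angles between consecutive v, Δv, Δ²v;
* w7–w9: angles between consecutive cross products p_n = v_n × v_{n+1},
  q_n = Δv_n × Δv_{n+1}, r_n = Δ²v_n × Δ²v_{n+1}.

Norms and angles are invariant under any fixed proper rotation R, and
cross products rotate covariantly ((Ra)×(Rb) = R(a×b)), so all nine
columns cancel sensor orientation exactly (verified to < 1e−9 over 100
random rotations in float64). The angle of a (numerically) zero vector
is defined as 0: stationary signals produce constant zero differences
and would otherwise flood the static postures with undefined values.

w9 consumes samples n…n+4, so all columns are truncated to the common
length N−4 per trial, indexed from the trial's first sample; a trial
must have at least 5 ticks. Features are used raw (no scaling).

Feature selection fits a CART decision tree and a 50-tree random forest
under both Gini impurity and information gain (scikit-learn), normalises
each ranking's importances to sum to 1, averages the four rankings, and
keeps the top k = 4 columns. On the synthetic cohort this reliably
selects {w1, w2, w3, w4}, matching the reference analysis. Rows are
subsampled to 20 000 for the rankers (seeded) to bound runtime.

## Windowing

Windows of W consecutive feature rows at stride s (default 1) are cut
per participant and per trial; a trial shorter than W contributes zero
windows and a logged warning. Each window takes the label of its last
row. Consecutive stride-1 windows share W−1 samples; the overlap ratio
is (W−s)/W (clipped at 0). Printed overlap percentages are truncated —
not rounded — to two decimals (44/45 → 97.77), matching the published
table convention. A bookkeeping helper reproduces the per-window-length
mean ± SD of LOSO training/test window counts from per-trial row counts
alone.

## Classifier

The reference architecture is, in order: conv(512, k5) → dropout 0.3 →
avgpool 3 → conv(256, k3) → dropout 0.3 → conv(64, k3) → avgpool 3 →
conv(128, k3) → conv(256, k5) → dropout 0.3 → conv(512, k7) →
dropout 0.3 → avgpool 3 → LSTM(512, tanh) → dense 100 → dense 28 →
dense 64 → dense 6 (softmax); all convolutions stride-1, "same"-padded,
relu. With 4 input features it has 3 715 830 trainable parameters
(regression-tested). The unusual dense ordering (100 → 28 → 64 → 6) is
reproduced verbatim.

The network is implemented directly in NumPy (float32): im2col
convolutions routed through BLAS, ceil-mode "same" average pooling that
averages only valid cells, a BPTT LSTM returning its last hidden state,
inverted dropout, and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−7). Weights are
Glorot-uniform, LSTM forget bias 1, all deterministic under the seed.
Loss is categorical cross-entropy, the standard pairing with a softmax
output. Ceil-mode pooling keeps any window length W ≥ 1 representable
(the reference sweep starts at W = 5, which three ÷3 poolings reduce to
a single LSTM step).

Checkpointing: `best_on_holdout` restores the weights with the best
holdout accuracy. The holdout defaults to a split carved from the
*training* participants; selecting on the test set (the reference
protocol) is available via `holdout_source="test_set"` but leaks test
information, so it is not the default. Desk-scale sweeps use
`checkpoint_policy="last"`, trading a possible small accuracy gain for
speed and simplicity.

`CNNLSTMClassifier` follows scikit-learn conventions (3-D input
`(n_windows, W, n_features)`, `fit`/`predict`/`predict_proba`/`score`,
`get_params`/`set_params`, trailing-underscore fitted attributes).

## Evaluation

LOSO: one fold per participant; folds partition the cohort. Per fold the
confusion matrix (rows = true, columns = predicted, fixed class order)
yields accuracy = trace/total and per-class precision, recall and F1;
zero-denominator cases are defined as 0. Per-activity metrics are
averaged across participants with equal weight (not pooled over
windows), matching the inter-participant design. The sweep repeats the
full LOSO procedure for each window length; a grid point that fails is
recorded and the sweep continues. Saturation is the smallest grid W
after which every successive mean-accuracy increment is below
ε = 0.01.

## Desk-scale study conditions

Full-scale training (42 participants, 65-minute protocol, 500 epochs,
batch 2000) is cluster-scale. The package's tested configuration — the
"desk" profile — keeps every pipeline stage identical and scales three
things, chosen once as the largest configuration that trains in minutes
on a single CPU:

* cohort of 8 participants with protocol durations × 0.02 (78 s each,
  ≈2 340 ticks at 30 Hz, ≈2 000 windows per participant at W = 35);
* conv filters and LSTM units ÷ 8 (70 286 parameters at 4 features);
* 10 epochs, batch 256, learning rate 0.003, stride-1 windows,
  window grid {5, 35, 55}.

Under these conditions the LOSO sweep reproduces the qualitative
structure of the full-scale study: mean accuracy ≈ 0.62 at W = 5 rising
to ≈ 0.82 at W = 35 and ≈ 0.84 at W = 55 (seed 1), far above the 1/6
chance level; walking and the running intensities are recovered almost
perfectly while sitting is poorly separated from lying — the same
hardest-class pattern as in real data. These numbers are label-recovery
results on synthetic data and are not estimates of real-data accuracy.

## Numerical choices and edge cases

* Angle computation clamps the normalised dot product to [−1, 1];
  zero-norm vectors (< 1e−12) yield angle 0.
* Resample tick counts use `floor(span·rate/1000) + 1` computed via
  multiplication to avoid float-division off-by-one at exact spans.
* Simulated timestamps that would round onto the next trial's first
  tick are dropped to keep timestamps strictly increasing.
* Sigmoid inputs are clipped to ±60 before `exp` (float32-safe;
  saturation beyond that range is exact anyway).
* Windows are float32 throughout the model path; features are computed
  and stored in float64.

## Known limitations

* No class rebalancing (deliberate; the protocol's lying share is
  larger, and the full-scale analysis kept the imbalance too).
* The generator's separability is controlled by a handful of amplitude
  parameters; it cannot calibrate absolute accuracies against real
  recordings.
* Training the full-scale ("paper") profile is supported but not
  exercised by the test suite; it is hours-to-days of CPU time.
* Single accelerometer, single wear position, no gyroscope channels.
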