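# pockethar

Orientation-invariant human activity recognition (HAR) from a single
pocket-worn smartphone accelerometer, built to study one question: **how
does the sliding-window length fed to a 1D-CNN-LSTM affect recognition
accuracy under leave-one-subject-out (LOSO) evaluation?**

A phone in a pocket sits in an arbitrary, participant-specific
orientation, so raw axis values are not comparable across people. The
pipeline cancels orientation with nine per-sample heuristic features of
the acceleration vector v_n and its time differences
Δv_n = v_{n+1} − v_n, Δ²v_n = v_{n+2} − 2v_{n+1} + v_n:

    w1 = ‖v_n‖        w4 = ∠(v_n, v_{n+1})        w7 = ∠(p_n, p_{n+1}),  p_n = v_n × v_{n+1}
    w2 = ‖Δv_n‖       w5 = ∠(Δv_n, Δv_{n+1})      w8 = ∠(q_n, q_{n+1}),  q_n = Δv_n × Δv_{n+1}
    w3 = ‖Δ²v_n‖      w6 = ∠(Δ²v_n, Δ²v_{n+1})    w9 = ∠(r_n, r_{n+1}),  r_n = Δ²v_n × Δ²v_{n+1}

All nine are exactly invariant under any fixed rotation of the sensor
frame. Impurity-based ranking (CART + random forest, Gini and
information gain) selects the top four; streams are resampled to 30 Hz,
cut into stride-1 windows of length W labeled by their last sample
(overlap ratio (W−1)/W), and classified by a hybrid network of six 1-D
convolutions, three average poolings, four dropouts, a 512-unit LSTM and
four dense layers ending in a 6-way softmax — implemented directly in
NumPy (no deep-learning framework required).

Because raw cohorts of this kind are usually not redistributable, the
package includes a first-class synthetic cohort generator: 42
participants by default, each performing a fixed 9-trial 65-minute
protocol (lying, sitting, walking, running at 3/5/7 METs) with an
arbitrary fixed device orientation, irregular 5–19 Hz sampling, and
missing spans. See `docs/methods.md` for the generative model and its
limits.

## Worked example

```python
import numpy as np
import pockethar as ph

# 1. simulate a small cohort (8 participants, shortened protocol)
cohort = ph.simulate_cohort(8, seed=1, duration_scale=0.02)

# 2. resample to 30 Hz and extract the nine invariant features
feats = [ph.extract_features(ph.resample_fixed(r)) for r in cohort]

# 3. impurity-based selection of the top four features
X = np.concatenate([f.values for f in feats])
y = np.concatenate([f.labels for f in feats])
top = ph.select_top_features(X, y, k=4, random_state=1)
print([ph.FEATURE_NAMES[i] for i in top])
# ['w2', 'w1', 'w4', 'w3']

# 4. LOSO sweep over three window lengths with the desk-scale model
report = ph.sweep_window_lengths(
    [f.select(top) for f in feats], [5, 35, 55], seed=1,
    estimator_params=dict(architecture="desk", epochs=10, batch_size=256,
                          learning_rate=0.003, checkpoint_policy="last"),
)
print(report.summary)
#    window_length  mean_accuracy  sd_accuracy
# 0              5       0.619500     0.021805
# 1             35       0.819171     0.025770
# 2             55       0.838977     0.030625
```

Mean LOSO accuracy climbs from 0.62 at W = 5 to 0.84 at W = 55 (chance
is 1/6 ≈ 0.17): short windows cannot separate the static postures,
whose invariant-feature statistics differ only weakly, while longer
windows saturate. `report.activity` holds per-activity precision,
recall and F1 averaged over participants — walking and the three
running intensities are recovered almost perfectly, sitting is the
hardest class.

The same pipeline is scriptable from the shell:

```bash
pockethar --profile desk --seed 1 --output-dir runs/demo run-full
pockethar --profile desk --seed 1 --output-dir runs/demo report   # figures
```

`--profile paper` switches to the full-scale configuration (42
participants, full 65-minute protocol, 512-filter network, 500 epochs,
batch 2000) — a cluster-scale computation.

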