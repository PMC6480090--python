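# Methods

## Problem and model

The task is binary classification of fixed-length windows of triaxial
acceleration into *fall* (positive, class index 1) and *ADL* (activity of
daily living, negative).  A window is an L×3 matrix; L is a property of the
recording protocol (500 for the URFD-style set-up, 25 for SmartWatch-style,
118 for Notch-style) and is treated as a unitless row count — no sampling
rate is assumed and unevenly sampled traces are not resampled.

Three convolutional variants share one declarative layer vocabulary:

| variant     | feature extractor                                | head          |
|-------------|--------------------------------------------------|---------------|
| CNN-3B3Conv | [conv×3 (k=4) → maxpool → dropout] + [conv×3 (k=3) → maxpool → dropout] | dense 64→32→2 |
| CNN-3Conv   | conv×3 (k=4) → maxpool → dropout                 | dense 64→32→2 |
| CNN-1Conv   | conv×1 (k=4) → maxpool → dropout                 | dense 64→32→2 |

Every conv layer has 64 filters, ReLU activation, and an L2 penalty of
α = 0.01 on its kernel weights (biases unpenalized); pooling is maxpool of
size 3 (non-overlapping, trailing remainder dropped); dropout probability
is 0.35, placed after each pooling layer and nowhere else.  Convolutions
are valid (no padding) with stride 1, so a layer maps length n to
n − k + 1 and a pool maps n to ⌊n/3⌋.  For L = 500 the CNN-3B3Conv chain is
497, 494, 491 → 163 → 161, 159, 157 → 52, giving 52 × 64 = 3328 flattened
features and 285,986 trainable parameters.

The two output neurons are read through a softmax.  The output activation
is a design choice (the architecture fixes only "two neurons"): softmax
gives the scores a probabilistic reading and a well-defined argmax
decision, with ties broken toward ADL so that an uninformative model does
not raise alarms.  Targets are one-hot and the loss is the mean
elementwise log-cosh between the softmax output and the target, plus the
L2 terms.  log cosh(r) is computed as |r| + log(1 + e^(−2|r|)) − log 2,
which is exact and overflow-free for any residual.

## Training recipe

Stochastic gradient descent with Nesterov momentum: learning rate 0.0107,
momentum 0.999, learning-rate decay 10⁻⁶ applied per update as
lr_t = lr₀/(1 + decay·t), 20 epochs.  Batch size is not part of the
published recipe; the default is 32.  Weights are Glorot-uniform
initialized.  All randomness — initialization, epoch shuffling, dropout
masks — derives from one `TrainConfig.seed`, so identical calls give
bitwise-identical loss histories.

Two empirical properties of this recipe are worth knowing.  With momentum
0.999 the velocity integrates roughly a thousand gradients, so epoch-level
loss is **not** monotone: it oscillates with a period of several epochs
while trending down (the test suite asserts net improvement over 20
epochs, not per-epoch descent).  Second, convergence is sensitive to the
*total update count*: on the bundled synthetic task runs of up to ~800
updates (800-window training set × 20 epochs at batch 32) converge
reliably, while much longer runs can overshoot late in training and
collapse to a single-class predictor.  This is a property of the recipe,
which is kept as published; users training on larger sets may prefer a
smaller momentum or larger batch via `TrainConfig`.

## Rotation augmentation

A new window is generated from an original by applying one rigid rotation
to every sample: aᵣ(t) = R·a(t) with R = R_z(γ)·R_y(β)·R_x(α),
right-handed elementary rotations, and α, β, γ drawn independently and
uniformly on [0, 2π).  The composition order, handedness and angle
distribution are fixed conventions chosen for reproducibility (the
maximal-entropy reading of "random rotation"); rotations preserve
per-sample norms to 10⁻⁹, which the suite verifies, so the label is
preserved by construction.  One rotation per copy, not per sample: the
whole measurement sequence is rotated rigidly, emulating the same movement
recorded at a different sensor orientation.

Copy counts are inputs (`AugmentPlan`), with three presets derived from
the study protocols' before/after arithmetic:

* `urfd` — 60 copies per fall, 80 per ADL, originals **not** carried over:
  30 falls + 40 ADLs → exactly 1800 + 3200 = 5000 generated windows, of
  which 80 % (4000) train and 20 % (1000) test.
* `smartwatch` — 5 copies per fall, none per ADL, originals kept:
  182 falls → 1092 fall sequences, 1088 ADLs untouched.
* `notch` — 4 copies per fall, originals kept: 106 falls → 530.

The URFD protocol's augmented set consists of the generated windows alone —
that is the only reading under which its printed totals (5000, and the
4000/1000 split) are arithmetically consistent — hence the
`include_originals` flag, default `True`, set `False` in that preset.

Augmentation happens before the train/test split and before normalization.
This mirrors the published ordering and means rotated copies of one parent
can land on both sides of the split; consequences for leakage are the
protocol's, not the implementation's.

## Normalization and splitting

Per-channel (x, y, z separately) min–max normalization maps v to
(v − min)/(max − min).  The extrema are fitted on the training split only
and applied unclipped to both splits, so held-out values may leave [0, 1];
a constant channel maps to 0 and is flagged degenerate.  Fitting on the
training split prevents test-set leakage; the alternative orderings the
protocol's wording would allow are not distinguishable from the text, so
the leak-free one was chosen.  Splits shuffle with a seeded generator;
the train size is round-half-away-from-zero of fraction·N (so 0.8 × 5000
= 4000 exactly).

## Evaluation

Accuracy, precision, sensitivity, specificity and MCC are computed from
the TP/FP/TN/FN tally with fall as positive.  Any ratio with a zero
denominator is reported as 0 with an `undefined` flag instead of raising,
keeping batch evaluation total while preserving honesty; MCC is likewise
0-flagged when any marginal of the table is empty.  Reports format
percentages to two decimals and MCC to four.

## The synthetic-data generator

The simulator exists to exercise the method end to end, not to model real
falls.  ADL windows are ‖a‖ = g + A·sin(2πt/T + φ) + ε with defaults
g = 1 g, A = 0.4 g, T = 10 samples, ε ~ N(0, 0.05 g); fall windows run
pre-fall activity → linear descent to a free-fall floor of 0.1 g → a
single impact sample drawn uniformly from 3–6 g → rest at gravity, with
randomized phase boundaries.  The magnitude profile is mapped onto a
random fixed orientation per window, so the three channels individually
carry no fixed meaning and rotation augmentation has real work to do.
The impact and deepest free-fall samples carry no additive noise, so every
fall window provably reaches ≥ 3 g and dips ≤ 0.3 g under the defaults.

Under the default configuration a bare threshold on max ‖a‖ separates the
classes at ≥ 99 % — they are learnable by design.  Passing tests on this
generator therefore shows the pipeline is wired correctly and the
optimizer can fit a separable signal; it says nothing about accuracy on
real recordings, where inter-class overlap, sensor artifacts and
unbalanced activity mixes dominate.  Harder distributions can be simulated
by narrowing the gap between `adl_osc_amplitude`, `fall_impact_peak` and
`noise_sd`.

## Problem sizes used in the checks

The bundled end-to-end checks run the CNN-1Conv variant at L = 25 with
800 training / 200 test windows (20 epochs, ~1 s on one CPU), the scale at
which the published recipe converges reliably.  Dataset bookkeeping for
the three presets is verified at the full published counts (5000, 1092,
530) on L = 25 windows, since the arithmetic is independent of window
length.  The rotation-augmentation benefit is measured as an equal-budget
comparison: both arms train on 800 windows (one arm all originals, the
other 400 originals + one rotated copy each) and are evaluated on a
rotation-perturbed held-out set over three seeds.  Equal training budgets
isolate the value of augmentation from the recipe's sensitivity to the
update count described above.

## Known limitations

* The network engine is single-threaded numpy; training CNN-3B3Conv at
  L = 500 on thousands of windows is possible but slow.  The architecture
  itself is validated structurally (layer census, shape chain, parameter
  count) and the training dynamics are exercised on the short-window
  variants.
* No AUC/ROC, no multi-class activity recognition, no streaming or
  messaging deployment layer.
* The simulator makes no biomechanical fidelity claims; see above.
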