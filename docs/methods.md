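# Methods

## The model

`saepso` implements a classification framework for numeric feature tables
(EEG epochs, clinical attribute vectors, imaging features) built from three
stages.

**1. Stacked sparse auto-encoders.** Each auto-encoder maps inputs
`x ∈ [0,1]^N` through a logistic-sigmoid hidden layer
`h = σ(W₁x + b₁)` and reconstructs them with a second sigmoid layer
`x̂ = σ(W₂h + b₂)` (untied decoder).  Training minimizes

```
E = (1/n) Σₙ Σₖ (x_kn − x̂_kn)²  +  λ·Ω_weights  +  β·Ω_sparsity
Ω_weights  = ½ (‖W₁‖²_F + ‖W₂‖²_F)            (biases excluded)
Ω_sparsity = Σᵢ ρ log(ρ/ρ̂ᵢ) + (1−ρ) log((1−ρ)/(1−ρ̂ᵢ))
```

where `ρ̂ᵢ` is the mean activation of hidden unit `i` over the full training
batch and `ρ` is the target sparsity proportion.  The leading `1/n`
normalizes over samples only; the inner sum over features is not
additionally normalized.  The KL term uses natural logarithms.  Two
auto-encoders are pretrained greedily — the second on the first's encoding —
so feature width shrinks gradually (e.g. 44 → 40 → 35), then the encoder
halves are stacked under a Softmax layer and the whole network is fine-tuned
on categorical cross-entropy.

**2. Particle swarm optimization.** A standard gbest swarm on a bounded box:

```
V ← w·V + c₁ r₁ (pbest − X) + c₂ r₂ (gbest − X);   X ← X + V
```

with `r₁, r₂ ~ U(0,1)` drawn per particle, per dimension, per iteration.
Inertia `w` decreases linearly from 0.9 to 0.2 over the run (the published
tables label these "min" and "max" inconsistently; the decreasing schedule
is the classic explore-then-exploit choice).  Velocities are clamped to
±`vmax_fraction·(high − low)` (default 0.2) and positions clipped to the
bounds; both guards are standard and prevent divergence.  The best cost per
iteration is recorded; it is non-increasing by construction.

**3. Linear output calibration.** The network's continuous class
probabilities `Ẑ` are corrected by

```
Z = A·Ẑ + B·X + e,    A = diag(a₁…a_M),  B ∈ ℝ^{M×N},  e ∈ ℝ^M
```

fitted by PSO to minimize `MSE = mean((Q − Z)²)` against the one-hot targets
`Q`, averaged over all samples × classes entries (the normalization does not
change the argmin).  The PSO searches the packed vector
`[a_diag ‖ B row-major ‖ e]` (dimension M + M·N + M) inside `[−5, 5]` per
coordinate — adequate because `Ẑ` and the scaled features lie in `[0, 1]`.
One particle is seeded at the identity transform `(A=I, B=0, e=0)`, so by
gbest monotonicity the fitted model never has a higher training MSE than the
uncalibrated outputs.  Class decisions are the row argmax with ties broken
toward the lowest index.

## Evaluation protocol

Ten confusion-matrix statistics are reported: recall, TNR, precision, NPV,
FPR, FDR, miss rate, accuracy, F1 and MCC.  Binary problems take class 1
("abnormal") as positive; multiclass problems macro-average one-vs-rest
values so small classes weigh equally.  Cells with a zero denominator return
0 with a logged warning rather than crashing on tiny test splits.

`repeated_holdout_eval` runs five (configurable) stratified random
train/test splits.  Per repeat the full pipeline is retrained from scratch;
min-max scaling statistics, imputation medians and the calibration model are
all fitted on the training split only and applied frozen to the test split.
The raw network and the calibrated network are compared with a two-tailed
paired t-test, `t = mean(d)/(sd(d)/√n)` with `n−1` degrees of freedom,
pairing every per-repeat metric value of one system with its counterpart in
the other.  Zero-variance differences are a degenerate input for the test
itself; when every repeat produces an identical metric table the protocol
reports `t = 0, p = 1` (no evidence of a difference) with a warning.

## Numerical and design choices

- **Activations** are logistic sigmoid throughout; the sparsity penalty
  requires activations in (0, 1), and mean activations are clipped to
  `[1e−10, 1 − 1e−10]` before any logarithm.
- **Auto-encoder training** is deterministic full-batch L-BFGS with the
  analytic gradient, capped at the configured epoch count; weights start
  from a seeded uniform Glorot scheme `U(−r, r)`, `r = √(6/(fan_in+fan_out))`,
  biases at zero.  The same seed always returns bitwise-identical weights.
- **Fine-tuning** is full-batch heavy-ball gradient descent (default
  lr 1.0, momentum 0.9, 400 epochs).  Momentum is not cosmetic: after sparse
  pretraining the hidden units sit near the target activation with tiny
  variance, and plain small-step descent through two sigmoid layers moves
  too slowly to recover class information (measured as majority-class
  accuracy without momentum).  The Softmax layer starts at zero — a
  deterministic, convex warm start.  The lowest-loss parameters seen during
  the run are returned, so fine-tuning can never end worse than it started.
- **Preset fine-tuning budget** (100 epochs, lr 0.5) deliberately stops
  supervised training while residual training error remains.  Output
  calibration corrects an imperfect network; a network driven to zero
  training loss makes the identity transform already optimal and the
  comparison vacuous.  The benchmark studies this framework targets report
  raw-network accuracies of 0.82–0.86 — an under-trained regime, which the
  presets emulate.
- **Feature source for calibration** defaults to the deepest encoding: with
  raw 4096-feature inputs the PSO search space would be ~8000-dimensional,
  intractable for a 50-particle swarm; the encoded representation keeps the
  search small.  `original_input` is available as a configuration option.
- **Preprocessing**: per-feature min-max scaling to [0, 1] (sigmoid
  reconstruction targets must be interior); constant features map to 0.5;
  missing entries (`?` in files, NaN in memory) are median-imputed.

## Synthetic data

The generator emits Gaussian class-conditional features around centroids at
a configurable Euclidean separation: two classes sit at ±(s/2) along a
random unit direction; more classes occupy mutually orthonormal directions
scaled to s/√2, making every pairwise centroid distance exactly s.  With
separation s and unit noise the two-class Bayes error is Φ(−s/2).  Three
presets mirror the benchmark shapes: `epilepsy-like` (200 × 4096, balanced
binary, s = 6), `spectf-like` (267 × 44, 187/80 imbalanced, s = 4) and
`arrhythmia-like` (450 × 279, 16 uneven classes, 5% missing, s = 6).  Label
counts follow the requested proportions exactly via largest-remainder
rounding.

What this emulates — and what it does not: the synthetic sets reproduce the
shapes, class imbalances and missing-data patterns of the real benchmarks,
so they exercise every pipeline stage end to end.  They are far simpler
than EEG waveforms or clinical attributes: features are independent
Gaussians, so a single linear direction separates the binary classes.
Passing tests therefore demonstrate the machinery (optimization, gradients,
protocol, non-degradation guarantees), not clinical-grade accuracy on real
recordings.

A second fixture supports the calibration stage in isolation:
`make_linear_fixture` draws simplex-distributed `Ẑ`, uniform features, a
known model `(A*, B*, e*)` and emits `Q = A*Ẑ + B*X + e* + noise`.  Because
diagonal-A calibration decouples per class, per-class ordinary least squares
gives its exact global optimum — the independent oracle the PSO fit is
tested against (within 5% relative on noisy fixtures; it can never go
below it).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline on the
`spectf-like` shape (267 × 44, five repeats, 44 → 40 → 35 with the published
epoch caps), gradient checks on ≤ 8 × 6 instances, calibration-vs-OLS on
200-sample fixtures, and the swarm on the 5-D sphere with the published
50 × 30 settings.  The `epilepsy-like` shape (4096 features) is generated
and validated for shape and separability, but the 4096 → 2007 auto-encoder
(~16M parameters) is exercised only through its configuration preset —
training it adds nothing methodological over the 44-feature pipeline.

## Known limitations

- The calibration model is fitted on training-split outputs only and applied
  frozen to the test split.  Fitting it on test outputs would leak labels;
  reports of perfect post-calibration scores elsewhere are consistent with
  either protocol, and this package deliberately takes the leakage-free one.
- Macro-averaged MCC (multiclass) is the mean of per-class binary MCCs, not
  the generalized multiclass MCC.
- No mini-batch training, GPU support, denoising/convolutional variants, or
  alternative metaheuristics; the swarm is a single global-best topology.
- The paired t-test treats per-repeat metric values as matched samples;
  repeats share the underlying dataset, so (as in the protocol it follows)
  independence across pairs is approximate.
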