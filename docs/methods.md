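# Methods

## Problem setting

Motor-imagery (MI) brain–computer interfaces classify short multichannel
EEG trials into imagined-movement classes (here: left hand, right hand,
feet).  Imagined movement modulates the power of sensorimotor rhythms —
event-related desynchronization (ERD) attenuates mu-band (8–12 Hz)
oscillations over class-specific cortical areas.  MI datasets are small
(here 178 patterns) and high-dimensional (3,600 features), so model choice
and hyperparameters dominate the outcome.  This package implements a
complete experimental chain for that setting: wavelet-variance feature
extraction, GA wrapper feature selection, a two-step evolutionary
hyperparameter search over three shallow neural classifier families, a
Cohen's-Kappa evaluation protocol, and a frequentist + Bayesian comparison
suite.

## Feature extraction

Each electrode signal is cut into 20 overlapping segments; each segment is
decomposed by a 6-level discrete wavelet transform; every coefficient set
(one approximation and one detail set per level) is summarized by its
within-set variance; finally features are min–max normalized to [0, 1].

Design choices where the procedure leaves room:

* **Segment geometry.**  Defaults are 256-sample segments (1 s at 256 Hz)
  with step 40 over a 1,016-sample trial — the unique small integer
  geometry that yields 20 overlapping segments whose 6-level decomposition
  produces coefficient sets of sizes 128, 64, 32, 16, 8, 4.  All values are
  configurable through `MRAConfig`.
* **Wavelet and boundary.**  Daubechies-4 with periodized boundaries, so
  set sizes halve exactly at each level.  Any discrete wavelet in
  PyWavelets can be substituted.
* **Level labeling.**  The first (shallowest) decomposition stage produces
  the largest sets and carries the highest level label: a 256-sample
  segment's 128-coefficient sets are "level 6", the 4-coefficient sets
  "level 1".  The mapping lives in `MRAConfig.level_label` to avoid
  off-by-one drift.
* **Both coefficient types per level.**  The intermediate approximation of
  every stage is retained alongside the detail set (not only the final
  approximation), giving 2 sets per level and 2·S·E·L = 3,600 sets total
  with the default geometry (504 coefficients per segment, 151,200 per
  trial).
* **Normalization scope.**  Min–max ranges are fitted on training data
  only and applied to test data with clipping to [0, 1]; constant training
  columns map to 0.  This prevents information leaking from test data into
  the scaling.

## Classifier families

All three families are deliberately shallow and trained by mini-batch
stochastic gradient descent on the softmax cross-entropy, with analytic
numpy gradients (verified against finite differences in the test suite):

* **FFNN** — 1–2 dense hidden layers (default ELU activation; ReLU tends
  to stall on these features), optional inverted dropout.
* **1-D CNN** — one valid-mode convolutional layer (true convolution: the
  kernel is flipped; border positions are discarded, so an input of width
  d with filter size k yields d − k + 1 positions), flatten, dense softmax
  output.  Default ReLU.  No pooling layer in the optimized architecture;
  stride is 1.
* **GRU** — the feature vector is read as a univariate sequence (one
  feature per time step; `step_size` allows block chunking) through a
  single GRU layer; the classifier head applies the configurable
  activation (default ReLU) to the final hidden state before a dense
  softmax layer.  The candidate state uses the convention
  `h~ = tanh(Wh x + Uh (r∘h_prev + bh))` — the bias sits inside the
  recurrent product; with all-zero weights one step halves the previous
  state.

Training choices left open by the procedure:

* **Optimizer.**  Plain SGD at the genome's learning rate, batch size 16.
  Gradients are clipped to a global norm of 5 — without clipping, learning
  rates in the upper part of the allowed (0, 1] range diverge on some
  initializations, which would make candidate quality depend on the
  initialization seed rather than on the hyperparameters themselves.
  A run that still produces a non-finite loss raises; searches score such
  candidates as fitness 0, and the pipeline's final evaluation records
  kappa 0 for a diverged repetition.
* **Initialization.**  Fan-in-scaled normal weights
  (SD = 1/sqrt(fan_in)), zero biases, fully seeded.

## Genetic searches

One generic engine drives all three searches: binary tournament selection,
a generational scheme producing `population_size` offspring per
generation, and elitist replacement (merge parents and offspring, rank by
fitness, truncate; ties keep incumbents).  Fitness is stratified 5-fold
cross-validated accuracy; each distinct genome is evaluated once and
cached, so the recorded best fitness is non-decreasing by construction.
Crossover and mutation probabilities default to 0.9 and 0.1 per offspring.

* **Feature selection** (binary genome, one bit per feature): uniform
  crossover preserving common bits, single-bit-flip mutation, and a repair
  step that enforces 1 ≤ active ≤ 30 after every operator (uniformly
  clearing excess bits keeps the surviving set a subset of the original).
  Initial active counts are drawn uniformly from [1, max_active] — the
  uncapped variant would start far outside the feasible region.  The
  wrapped classifier defaults to logistic regression (cheap enough for the
  1000 × 100 search budget) and is pluggable.
* **Structure search** (real-coded): genes are initialized from
  Normal(mid-range, range/6) so ±3 SD spans the range, clamped, rounded
  for integer genes, filter sizes forced odd (and additionally capped by
  the input width).  CNN/RNN use single-point crossover (degenerate for
  the length-1 RNN genome: the child copies a random parent) and
  multiplicative Gaussian mutation (one gene × Normal(1, 0.1)).  FFNN
  structures are variable-length (depth 1–2, drawn uniformly at
  initialization, widths initialized up to 200 but uncapped during the
  search): midpoint crossover joins the first half of one parent with the
  last half of the other; mutation applies the Gaussian factor to one
  layer or to all layers (50/50).
* **Learning search** (real-coded; learning rate ∈ (0, 1], epochs ∈
  [1, 200], dropout ∈ [0, 0.9] for FFNN only): single-point crossover and
  Gaussian mutation; for the FFNN, mutation chooses 50/50 between the
  generic gene mutation and a dropout-specific one.

**Two-step procedure.**  Step 1 searches structure with fixed baseline
training parameters (60 epochs, learning rate 0.1 — the same baseline the
unoptimized reference models use); step 2 freezes the best structure and
searches the learning parameters.  The full budget is 40 individuals × 10
generations per step.

**Fitness noise.**  With ~120 training patterns, one 5-fold CV estimate
has a standard error of several accuracy points, and a search that
maximizes a noisy estimate overstates its winner.  `GAConfig.cv_repeats`
averages the fitness over that many CV fold seeds (default 1; the
scaled-down experiments below use 2).

## Evaluation and comparison

Cohen's Kappa corrects observed accuracy p0 for the chance agreement pc of
the confusion-table marginals: κ = (p0 − pc)/(1 − pc) ∈ [−1, 1].
Experiments train a final model repeatedly (default 15 repetitions, seeds
base..base+n−1) and report mean ± SD and best κ.  Synthetic experiments
use a stratified 70/30 train/test split.

The comparison suite takes a matrix of κ observations (runs × datasets in
rows, methods in columns):

1. **Friedman test** on within-row ranks (average ranks on ties, classic
   tie correction, df = k − 1) gates everything at α = 0.05.
2. **Wilcoxon signed-rank** (two-sided) per pair: zero differences
   dropped, average ranks on ties, exact tie-aware null distribution by
   dynamic programming for n ≤ 25, otherwise a normal approximation with
   continuity and tie corrections; **Holm** step-down adjustment across
   the pairs.
3. **Bayesian signed-rank with a rope** (region of practical
   equivalence, default ±0.01 on the κ scale): paired differences are
   counted as left / rope / right of the rope, a Dirichlet posterior is
   built on the counts with one prior pseudocount in the rope (preventing
   a degenerate posterior when a count is zero; a zero-count coordinate
   with no prior mass is sampled as exactly zero via gamma draws), and
   2,000 sampled triplets yield the probability that each outcome
   dominates (fraction of samples where that coordinate is the maximum,
   ties split; the posterior-mean triplet is also recorded).  Triplets map
   affinely to barycentric coordinates in an equilateral triangle (left
   vertex: b − a < 0, right: b − a > 0, apex: rope) for the usual simplex
   heatmap.

The count-based Dirichlet construction is simpler than the full
Dirichlet-process signed-rank test; it is the construction implemented
here, deliberately.

## Synthetic data

Real MI recordings of this kind are not redistributable, so the package
generates data with the statistical structure the pipeline assumes.

* **Raw trials** (`generate_mi_trials`): 15 electrodes at 256 Hz, 1,016
  samples, 3 balanced classes.  Every electrode carries 1/f-colored noise
  (spectral shaping of white noise, exponent 1) plus a random-phase
  oscillation band-limited to 8–12 Hz.  For a trial of class c the
  oscillation on that class's three electrodes is attenuated by
  `erd_depth` (default 0.5) during the middle half of the trial — an
  ERD-like, class-informative band-power modulation.  What this does NOT
  emulate: volume conduction between electrodes, artifacts (blinks, EMG),
  non-stationarity across a session, or subject variability.  Passing
  tests therefore show the pipeline recovers the class signal it is
  designed for, not that it handles real recordings' confounds.
* **Feature-level fixtures** (`generate_feature_patterns`): right-skewed
  (lognormal) positive features min–max normalized to [0, 1], with a known
  subset of columns given class-dependent mean shifts of `effect_size`
  pooled-SD units between adjacent classes.  The benchmark suite fixes
  three of these: `null` (no informative features), `strong` (30
  informative of 200 at effect 0.7 — chosen so a default FFNN reaches a
  mid-range κ ≈ 0.7, comparable to the unoptimized baselines of the study
  design, while leaving genuine headroom for tuning), and `planted`
  (5 informative of 200 at effect 2.0, for selection-recovery tests).

## Problem sizes in the shipped experiments

The package's own experiments are scaled to run quickly on one CPU: the
feature-selection recovery uses 100 individuals × 30 generations on the
178 × 200 planted fixture; the two-step demonstration uses 16 × 6 per step
with `cv_repeats = 2` on the strong fixture and 5 evaluation repetitions.
The full study budgets (1000 × 100 for selection, 40 × 10 per optimization
step, 15 repetitions) remain the package defaults.

## Known limitations

* Networks are plain-SGD numpy implementations intended for shallow
  architectures and small datasets; there is no GPU path, and the GRU
  keeps its full unrolled trace in memory (fine for the ≤ 30-step
  sequences produced after feature selection, wasteful for 3,600 steps).
* Strict elitism is guaranteed for the cached fitness values; because CV
  fitness is itself a noisy estimate, the "best" genome is best under that
  estimate, not certainly best in expectation.
* The energy/time instrumentation of the original experimental design is
  hardware-bound and out of scope.
* LSTM recurrence is not implemented; the recurrent family is GRU only.
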