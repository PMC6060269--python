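# Methods

This note documents the models, the simulator, the numerical choices and the
known limitations of `spikebench`.

## Data model

All computation operates on a `BinnedDataset`: an aligned table of
time-binned covariates (position, velocity, heading, …) and per-neuron
nonnegative integer spike counts, with a fixed bin width (50 ms for the
kinematic analyses, 5 ms for history analyses, where refractory-scale
structure is resolvable). Spike counts in a bin are modelled as Poisson with
mean `μ_t` (counts per bin); models predict `μ_t` from the covariates.

## Scoring

**Poisson log-likelihood.** `L(y, μ) = Σ_t [y_t log μ_t − μ_t − log(y_t!)]`.
Predicted means are floored at `ε = 1e-10` *inside the logarithm only*, so
models that predict exactly zero are penalized heavily but finitely, while
the saturated model (`μ = y`) is scored without rounding error. The same
floor applies to every model.

**Deviance and pseudo-R².**
`D(y, μ) = 2 Σ_t [y_t log(y_t/μ_t) − (y_t − μ_t)]` with `0·log 0 = 0`;
`R² = 1 − D(y, μ_model)/D(y, μ_null)`. The deviance-ratio and
likelihood-ratio forms are algebraically identical; numerically they agree to
1e-10 in absolute terms for scores of ordinary magnitude, and to 1e-10
*relative* for badly misspecified models whose scores are far below zero
(pure floating-point cancellation). A null deviance of zero (constant data
perfectly fit by the null) raises `UndefinedScoreError` rather than returning
0/0.

**Cross-validation.** 8 folds by default. Per fold, the model trains on the
complement and is scored on the held-out bins against the *training-set* mean
as the null; the headline score is the mean of the fold scores (fold scores
are not pooled). Fold assignment is random for memoryless designs and
contiguous-in-time when history columns are present.

**Population summaries.** Per-neuron fold-mean scores are summarized by the
population mean with a percentile bootstrap CI (default 10,000 resamples,
95%). *Neurons* are the resampling unit — fold scores of one neuron share
data and are not exchangeable. Supported statistics: mean (e.g. of
per-neuron comparative scores), mean difference, and ratio of population
means.

## Models

All models satisfy one adapter contract: `fit(X, y)`, then `predict(X)`
returning strictly positive finite mean counts per bin; predicting before
fitting raises; fits are reproducible from an explicit integer seed.

**Poisson GLM (in-package).** `μ = exp(Xw + b)` minimizing the per-sample
negative log-likelihood plus an elastic-net penalty
`λ(α‖w‖₁ + (1−α)/2‖w‖₂²)` on internally standardized features, bias
unpenalized. Solver: monotone proximal gradient with backtracking line
search; the L1 term is handled exactly by soft thresholding. Convergence
when the relative objective change is below 1e-8 (non-convergence emits a
warning and is recorded on the results object, never silent). The problem is
convex, so the optimum is global. Default `λ = 1e-4, α = 0.5` in the
benchmark adapter; parameter-recovery analyses use `λ = 0`.

**Feedforward network (in-package, NumPy).** Two dense hidden layers with
batch normalization and ReLU, dropout after the first hidden layer, elastic
net on weights (not biases), and a final exponentiation; trained to maximize
the Poisson likelihood with Adam on shuffled mini-batches. With zero hidden
layers the architecture reduces exactly to the GLM. Defaults: hidden
(64, 32), dropout 0.1, L2 1e-4, learning rate 1e-2, 60 epochs, batch 256.
Initialization, shuffling and dropout all derive from one seed, so training
is bit-reproducible; across seeds, scores vary within ordinary optimization
tolerance and comparisons should use score tolerances, not bit equality.

**Gradient boosted trees.** XGBoost with `objective="count:poisson"`,
exposing the standard tuned hyperparameters (number of trees, max depth,
min child weight, subsample ratio, min split gain, learning rate); defaults
200 trees, depth 3, learning rate 0.1, `n_jobs=1` for determinism.

**Random forest.** scikit-learn bagged regression trees. The forest
minimizes squared error, which is not the proper loss for Poisson counts; it
is included as ensemble input for diversity, and its zero predictions are
floored at `ε` like every other model's.

**Hyperparameter tuning.** Seeded random search over a declared space,
scored by validation pseudo-R² on a held-out fraction of the data supplied
for tuning. Callers must pass data disjoint from the final test folds; the
returned trials table records every configuration evaluated. (A Bayesian
optimizer can be slotted in by replacing the search loop; random search is
the deterministic, dependency-free default.)

**Stacked ensemble.** A second-stage boosted-trees model trained on the
first-stage models' *predicted rates* (not log rates). Nested CV: for each of
the 8 outer folds, an inner k-fold CV (k = 5 by default; k is a documented
choice, balancing out-of-fold coverage against compute) over the outer
training set produces out-of-fold first-stage predictions that train the
second stage, while first-stage models refit on the whole outer training set
produce its test inputs. Every prediction's provenance (which model, trained
on which bins, predicting which bins) is recorded, and `audit()` verifies
two invariants: no ensemble-training prediction comes from a model that saw
that bin, and no outer-test bin appears in any training set — including
inside causal history windows. An audit failure is a hard error, never a
score.

## Temporal history features

Raised-cosine bases follow the log-time-stretched construction standard in
the spike-train GLM literature: basis k is `0.5 cos(u − φ_k) + 0.5` on the
warped axis `u = log(t + c)`, clamped to zero outside `|u − φ_k| < 2d`
(`d` = peak spacing), sampled at lags 1..L bins and peak-normalized to 1.
The log offset is `c = bin_width`; the first peak sits at one bin and the
last is placed so the final basis decays to zero exactly at the span
(250 ms over 5 ms bins → a 50 × 10 basis matrix). These constants are this
package's defaults, not values inferred from any particular prior study.
Early bases are narrow (refractory timescales), late bases broad
(adaptation); their sum is near-constant over the span's interior
(coefficient of variation < 0.2), so the filter space tiles time evenly.

History designs contain the current covariates, each covariate convolved
with each basis, and the neuron's own past counts convolved with each basis
(10 covariates × 10 bases → 120 columns). Convolutions are strictly causal:
the column value at bin t depends only on bins ≤ t−1, so a model can never
see the count it is predicting. With contiguous folds, a guard margin of one
filter length is removed from the training side of every train/test boundary
(both sides, conservatively — only the trailing side is strictly required
for causal filters), so training rows' history windows cannot overlap test
bins.

## Other feature transforms

- **Movement direction** is the four-quadrant angle of (vx, vy) in (−π, π].
  Direction is undefined at zero speed; those bins deterministically get
  θ = 0 and a boolean mask is returned so callers may drop them.
- **Trig direction** `(cos θ, sin θ)` linearizes cosine tuning for the
  exponential-link GLM (a weighted sum of sine and cosine is a phase-shifted
  cosine).
- **Engineered kinematics**: the fixed 10-column set
  `x, y, vx, vy, cos/sin(velocity direction), speed, radial distance,
  cos/sin(position direction)`.
- **Place fields**: squared Mahalanobis half-distances
  `p_k = ½(x − μ_k)ᵀ Σ_k⁻¹ (x − μ_k)` to a uniform 5 × 5 grid of centers
  over the occupied bounding box, with isotropic Σ whose standard deviation
  equals the grid spacing (chosen for uniform tiling). An exponentiated
  nonnegative combination of the p_k is a single Gaussian bump centered
  anywhere between the grid points, which is what makes place tuning
  learnable by an exponential-link GLM.

All transforms are stateless and deterministic with documented column order.

## The simulator

Trajectories are not prescribed by any dataset the package ships; the
generators aim for qualitative realism with the simplest adequate processes:

- **Center-out reaching**: hold–reach–hold–return cycles to 8 equally spaced
  targets on a 10 cm ring, minimum-jerk speed profiles, per-trial duration
  jitter, 50 ms bins. Velocities are central finite differences of position,
  so position/velocity consistency is exact by construction.
- **Foraging**: an Ornstein-Uhlenbeck velocity process (correlation time
  1 s, RMS speed 0.2 m/s) with reflecting walls in a 1 m × 1 m arena; long
  sessions visit every cell of a 5 × 5 partition, so all place fields are
  excitable.

Neuron ground truth is a `NeuronSpec` (tuning kind + parameters + seed);
counts are Poisson draws from the spec's rate evaluated per bin.
History-kind neurons are generated sequentially, the log rate modulated by a
causal filter over their own already-generated counts, which produces
refractory suppression at 5 ms resolution. Each neuron draws from an
independent substream keyed by (call seed, spec seed): datasets are
bit-reproducible and adding a neuron does not perturb the others.

**Calibration to realistic score scales.** Deterministic tuning plus Poisson
noise alone yields cross-validated pseudo-R² near the explainable ceiling
(≈ 0.2–0.3 at these rates), whereas published encoding scores on cortical
recordings are typically several-fold lower because real neurons carry
strong slow rate fluctuations unrelated to the measured covariates. Scenario
neurons therefore include a mean-corrected log-normal OU gain
(sd 0.8 for the reaching/pursuit scenarios, 0.3 for the hippocampal one,
correlation time 5 s) and heterogeneous modulation depths
(m ~ U(0.2, 1.2) for cosine tuning — populations include weakly tuned
cells). With these defaults, trig-feature GLM population means land around
0.08–0.12. The gain has unit mean, so the covariate-conditional rate — the
target an ideal encoding model can reach — is still the spec's tuning
function; the gain only lowers the attainable ceiling, identically for every
model. Hippocampal place cells use peak rates of 3–10 spikes/s and field
widths of 5–10 cm in a 1 m arena, so the median neuron fires well below
1 spike/s, matching the sparseness regime where squared-error methods and
networks struggle.

## What passing tests do and do not show

The simulator produces exactly Poisson counts given the (gain-modulated)
rate, perfectly aligned covariates, and stationary tuning. Real recordings
violate all three (non-Poisson dispersion beyond the modelled gain, tracking
and sorting noise, nonstationarity), so passing tests demonstrate the
*machinery* — scoring, leak-free CV, solver correctness, the qualitative
model-comparison phenomenology — not that any particular brain area behaves
like the generator. Conversely, because ground truth is known, the tests can
assert things impossible on real data: exact parameter recovery, oracle
ceilings, and guaranteed misspecification gaps.

## Problem sizes and numerical choices

Test analyses use 2,000–50,000 bins and 4–20 neurons: large enough that
sampling error is well inside the asserted tolerances (e.g. preferred
direction recovered within 5° needs only a few thousand spikes; stacking
comparisons at 50,000 bins hold to ±0.02), small enough to run on one CPU in
minutes. Ties and degenerate inputs are handled explicitly: zero-speed bins
get direction 0 plus a mask; constant data under the null raises
`UndefinedScoreError`; non-finite rates in the generator raise
`GenerationError` naming the offending spec; the GLM warns on
non-convergence.

## Known limitations

- No recurrent (LSTM) adapter; the adapter contract accepts one, but none is
  shipped.
- Random-search tuning only; no Bayesian optimizer.
- The random forest's squared-error objective is knowingly improper for
  counts; it is documented as ensemble input only.
- The network's batch-norm inference statistics come from exponential moving
  averages, so very short trainings can be slightly miscalibrated; use ≥ 10
  epochs.
- Bootstrap CIs resample neurons and therefore ignore fold-level correlation
  within a neuron; with very few neurons the CI is anti-conservative.
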