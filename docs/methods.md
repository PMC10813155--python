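# Methods

## Problem and model

`swayhmm` classifies quiet-standing balance recordings as healthy or
parkinsonian from raw center-of-pressure (COP) trajectories. A recording is
a sequence X = x_1 … x_n of displacement vectors (medial–lateral and/or
anterior–posterior channels, in mm). The generative model is a first-order
hidden Markov model λ = (π, A, B): a hidden chain z_1 … z_n over K sway
regimes with initial distribution π and transition matrix A, where state k
emits observations from a Gaussian mixture

    p(x | z = k) = Σ_j w_kj · N(x; μ_kj, Σ_kj),

with full covariances (so ML/AP correlation is modeled when d = 2). A single
component (w_k1 = 1) is the plain Gaussian-emission HMM.

Classification is the two-model likelihood rule: one HMM is trained on the
healthy cohort (H-HMM) and one on the PD cohort (PD-HMM); a test recording
is labeled healthy iff log p(X | H-HMM) > log p(X | PD-HMM). An exact tie —
which occurs in practice only when the two models are identical — is
resolved to PD, the clinically conservative call. Both log-likelihoods are
always returned so decisions can be audited. Likelihoods are compared as
totals (not per-sample averages); within a cohort all recordings share
length, so the comparison is unaffected, and the choice is documented here
because it would matter for mixed-length data.

## Inference and numerics

Likelihood evaluation uses the scaled forward recursion; posteriors use the
scaled forward–backward smoother; decoding uses Viterbi with ties broken
toward the lower state index (deterministic and testable). Over a 60 s
recording at 1000 Hz the raw likelihood underflows double precision by
thousands of orders of magnitude, so:

* emission densities are computed in log space (Cholesky-based Gaussian
  log-pdfs; a non-positive-definite covariance raises a model-validity
  error rather than propagating NaNs);
* the per-step emission row is shifted by its maximum before
  exponentiation, and forward/backward variables are renormalized at every
  step; the discarded log scale factors are accumulated into the
  log-likelihood;
* a pure log-space forward recursion (logsumexp at every step) is kept as a
  second code path and cross-checked against the scaled path to 1e-10 in
  the tests.

The recursions are compiled with numba; at minute-long sequence lengths the
Python-level loop would otherwise dominate the training time.

Exactness is established against a brute-force oracle that enumerates all
K^n hidden paths (guarded to K^n ≤ 1e6) and sums/maximizes their
complete-data probabilities in log space: forward likelihood, smoothed
posteriors and Viterbi paths must agree with enumeration to 1e-8 relative
on randomized small instances.

Higher-order chains are representable (the `order` field) but inference
rejects order > 1 explicitly; only first-order models are used. Discrete
emission tables are supported for likelihood evaluation and decoding, but
EM training is implemented for the Gaussian case the classifier uses.

## Training

**Initialization.** All training samples (pooled across subjects) are
clustered with K-means into n_states × n_components centroids, best of
`kmeans_restarts` (default 5) by inertia at a fixed seed. Centroids are
ordered lexicographically — K-means labelings are permutation-arbitrary, and
without a canonical order the init would not be a pure function of data and
seed — and assigned to states in contiguous blocks. Each component takes its
centroid as mean, the within-cluster covariance (floored) as covariance, and
a weight proportional to cluster size within its state; π and A start
uniform.

**EM.** Baum–Welch runs a fixed 15 iterations by default (`tol = 0`
disables early stopping; a positive tolerance enables it). The default
iteration budget, state count (3) and mixture count (2) are the protocol
settings this package replicates; the training log-likelihood plateaus well
within the budget on both simulated cohorts and the trajectories the
classifier logs. The M-step is the posterior-weighted update

    μ_k = Σ_i τ_ik x_i / Σ_i τ_ik,
    Σ_k = Σ_i τ_ik (x_i − μ_k)(x_i − μ_k)ᵀ / Σ_i τ_ik,

with τ generalized to per-component responsibilities for mixtures; mixture
weights are normalized responsibility mass; A is the row-normalized sum of
expected transition counts; π is the average of first-sample posteriors
across sequences. Multiple subjects are handled by summing expected
sufficient statistics across sequences — subject boundaries are respected
rather than concatenating recordings, which would fabricate transitions
between subjects.

**Numerical safeguards.**

* Covariance floor: after every update, covariance eigenvalues are clipped
  at `covariance_floor_scale` (default 1e-6) × the pooled per-channel data
  variance. Without it, EM on short or duplicated segments drives
  components singular.
* Starved components: a component whose responsibility mass falls below
  1e-10 is re-seeded at the sample the current model explains worst, with a
  warning; the standalone single-Gaussian M-step instead raises so callers
  control the policy.
* Any non-finite log-likelihood aborts with the iteration number.

The EM monotonicity guarantee (each iteration's total log-likelihood is no
lower than the last, 1e-6 relative tolerance) is asserted across 20 random
data/seed draws in the tests.

## Evaluation

Metrics follow the convention in which *healthy* is the positive class —
the reverse of common clinical usage, kept deliberately:

* sensitivity = % of healthy subjects classified healthy,
* specificity = % of PD subjects classified PD,
* accuracy = % of all subjects classified correctly.

Worked example: with 28/28 healthy correct and 31/32 PD correct,
sensitivity is 100%, specificity 31/32 = 96.875% and accuracy
59/60 = 98.33%. (Published summaries of these counts sometimes round to
96.8%/98.4%; the package reports the exact fractions and does not chase
printed rounding.)

Cross-validation is stratified k-fold (default k = 10): each class is
shuffled with the run seed and dealt to folds in one round-robin pass, which
preserves class proportions to integer resolution and degenerates correctly
to leave-one-out at k = n (the reason the fold assignment is implemented
here rather than with a library splitter, which rejects k above the smaller
class size). The confusion table is pooled over folds; the ± spread on
accuracy is the sample standard deviation of per-fold accuracies — reported
under that explicit name, since "±" conventions vary. A fold whose training
split loses a class entirely raises with the advice to lower k.

The hyperparameter sweep evaluates a (states × mixtures) grid with shared
fold assignments (same seed) so cells differ only in the model, and records
per-cell errors without aborting the sweep.

**Channel fusion.** For combined ML+AP classification the default is
bivariate emissions (d = 2, full covariance), which subsumes inter-channel
correlation. The alternative interpretation — independent per-channel HMM
pairs whose log-likelihoods are summed — is available via
`ClassifierConfig(channel_fusion=True)`.

## Synthetic cohorts

The simulator exists because clinical stabilometric cohorts are private; it
generates data with known ground truth so the full pipeline is testable.

* `hmm` mode (default): subjects are sampled from 3-state bivariate
  Gaussian HMM generators. The healthy base has state means a few mm apart,
  AP variance above ML variance, and ~2 s dwell times (self-transition
  0.995 at 100 Hz). One `separation` parameter moves the PD generator away
  from the healthy one: state means displaced proportionally, variances
  inflated ×(1 + 0.8·separation), dwell times shortened — larger, faster,
  less regular sway, a qualitative caricature of impaired postural control.
  `separation = 0` makes the generators identical, so cross-validated
  accuracy must fall to chance; this null is asserted with a central 99%
  binomial interval around 50%.
* `ar2` mode: each channel is a stable AR(2) process (roots checked inside
  the unit circle) with class-dependent damping and innovation scale. AR
  output is smoother and closer in texture to real COP traces, and gives a
  deliberately misspecified setting for the HMM classifier.

Defaults mirror the emulated study's geometry: 28 healthy + 32 PD subjects,
60 s per recording. The default rate is 100 Hz so the full 10-fold protocol
runs in a few minutes on one core; 1000 Hz is available via the config, and
the HMM is agnostic to the rate up to dwell-time rescaling. Separation
defaults to 1.0, which places matched states roughly two within-state
standard deviations apart — well-separated, but learned from finite data,
so it exercises the estimator rather than trivializing it.

What the simulator does **not** emulate: real COP spectra (fractal/long-range
correlation structure), nonstationary drift and fatigue, age and disease-stage
strata, or inverted-pendulum biomechanics. Passing tests therefore
demonstrate correctness of the estimator and protocol on data satisfying the
model's assumptions (and robustness to AR misspecification), not clinical
performance on real patients.

## Problem sizes used in the checks

Oracle comparisons run on 50 random instances with K ≤ 3, n ≤ 8. EM
monotonicity uses 20 runs of 3 × 400-sample bivariate sequences. Parameter
recovery uses 20 × 2000 samples from a well-separated 3-state bivariate
truth, requiring state means within 10% and transition probabilities within
0.1 after permutation alignment. The end-to-end protocol check runs the full
28 + 32 cohort at 100 Hz through stratified 10-fold CV with the default
settings, once with separated generators (accuracy ≥ 95% expected) and once
at zero separation (chance level expected).

## Known limitations

* Gaussian mixtures are a crude density model for sway; the classifier
  compares likelihoods, so shared misspecification partially cancels, but
  absolute likelihoods should not be over-interpreted.
* EM converges to local optima; determinism comes from the seeded K-means
  start, not from global optimization.
* The simulator's class differences are low-dimensional and generous
  compared to real cohorts; accuracy on synthetic data says nothing about
  clinical discriminability.
* Mixed-length cohorts would make total-log-likelihood comparison
  length-sensitive; per-sample normalization would then be worth exposing.
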