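# Methods

This note documents the models and procedures implemented in `metofs`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical decisions taken where the printed
formulas leave gaps.

## Optimizers

All three optimizers minimize a black-box objective over a box-bounded
real domain with a population of N candidates, an elitist best-so-far
record (never replaced by a worse solution; ties resolve to the lowest
row index), and projection (clipping) onto the original box after every
update.  Reproducibility is by construction: one uniform random stream
per run, and a stub stream that replays an injected draw sequence so
that unit tests can compare a full iteration against straight-line hand
arithmetic.

### ETO

Iterations t = 1..t_max split into exploration (t ≤ T, T = ⌊1.2 +
t_max/2.25⌋) and exploitation.  A changeover value
CM = 0.01·u·(t/t_max)^tan(d₁/d₂) picks the phase-1 rule when CM > 1 and
the phase-2 rule otherwise.  Notable properties of the printed
formulas, implemented as printed and flagged rather than "fixed":

* d₂ = −d₁ exactly, so the ratio d₁/d₂ is the constant −1 wherever
  defined and 0/0 at cosine zeros.  We use the guarded constant −1
  everywhere; consequently tan(d₁/d₂) = tan(−1) ≈ −1.557 and
  c = exp(tan(−1)) ≈ 0.2107 are constants, and the α₃ factor
  exp(|d₁/d₂|−1.3) is the constant e^(−0.3).
* CM > 1 requires t/t_max ≲ 0.05, so the phase-1 exploitation rule
  (which needs t > T ≈ 0.45·t_max) never executes in a plain run; the
  exploitation stage always uses the phase-2 rule
  Xᵢ ← Xᵢ + c·u·α₂·|X_b − Xᵢ|, a non-negative drift whose step vanishes
  as the population collapses onto X_b.  ETO's refinement therefore
  effectively stops after the exploration stage — visible in the sphere
  benchmark below.
* The constrained-exploration (CE) recurrence grows explosively, so at
  most one bound-adaptation event fires (at t = ⌊1 + t_max/1.55⌋).  The
  adapted bounds can come out inverted (LB > UB) when the best solution
  has negative coordinates; such events are skipped and logged.  Adapted
  bounds affect only the sampling scale of donor operators; feasibility
  clipping always uses the original box.
* α₂ contains two rand() factors; each is an independent draw.
* Draw convention (unstated in the source): branch choices q₁–q₄ are
  drawn once per solution, step magnitudes once per dimension, matching
  the element-wise subscripting of the update rules.

### AOA

MOA(t) = Min + t·(Max−Min)/t_max gates exploration (r₁ > MOA) vs.
exploitation per solution; MOP(t) = 1 − (t/t_max)^(1/α) scales the
operators.  α = 5 and μ = 0.5 as stated; Min = 0.2, Max = 0.9 are
common settings (the source gives none) and are configurable.  The
exploration rule is implemented with its printed scale term
((UB−LB)+LB), i.e. without μ; `AoaParams.mu_in_exploration` restores
the canonical form.  The division guard ε is 10⁻¹² (described as a
"small integer", which would defeat its purpose).  Note that the
exploitation step MOP·((UB−LB)·μ+LB) vanishes identically on any
origin-symmetric box with μ = 0.5 — one reason the benchmarks here run
on the unit box (see below).

### GLS

Visited populations accumulate in an experience buffer; once the
counter exceeds C_max, the dispersion
V₀ = mean_j[std_j(buffer)·200/(UB_j−LB_j)] (population 1/n convention)
decides the guidance move: V₀ > α jumps around the best solution with
per-element steps tan(R·π)·(UB−LB)/V₀ (Cauchy-tailed; R is resampled
within 10⁻⁹ of 0.5), otherwise a uniform restart LB + R·(UB−LB) (the
printed restart lacks the LB offset; it is added so non-zero lower
bounds stay in-box — identical on [0,1]).  New candidates are kept per
row only on strict improvement, then the buffer is cleared.  C_max =
10·N and α = 1.0 are this package's defaults (the source states
neither) and are configurable.

### METO

Per iteration: ETO bookkeeping; fitness shares P_i = Fit_i/ΣFit and
threshold rp = min P + u·(max P − min P); rows with P_i < rp take the
AOA operator of the current phase (Division/Multiplication when
exploring, Subtraction/Addition when exploiting, on the CE-adapted
bounds), the rest take
the ETO operator with CM selecting the phase-1/phase-2 variant.  Since
the fitness is a cost, *better* solutions have smaller shares and are
the likelier AOA takers — kept as printed.  Experience is recorded
every iteration; guidance is attempted when t ≡ 0 (mod 10), still
gated by C > C_max.  Forcing the injection off reproduces ETO bitwise
(same draw sequence); forcing it on makes every update an AOA operator.

## Wrapper feature selection

Positions live in [0,1]^D.  The default binarization thresholds at 0.5
(strict >); the literal coin-flip rule from the source description is
available as `binarization="literal-random"` but makes selection
independent of the position, severing the feedback loop between fitness
and search, so it is not the default.  All-zero masks are repaired by
forcing the highest-position coordinate.  The fitness is
ρ·γ + (1−ρ)·|BX|/D with ρ = 0.99 (error-dominant, standard wrapper
practice; the source states no value).  γ is measured on the validation
split; the test split is touched exactly once, by the final evaluation
of the best mask.  KNN uses K = 5, Euclidean distance on raw features
(the generators and the learned representation are already on a common
scale).  AUC uses the positive-neighbor vote fraction as the score
(K+1 distinct levels) with tie-aware rank AUC — the only score a KNN
provides without calibration.  Experiment aggregation reports
Mean/StD/Best/Worst with the population (1/n) standard deviation; for
feature counts, best is the minimum.

## Feature-extraction stack

Pearson FC per subject (symmetric, unit diagonal; constant ROIs are
flagged and their correlations set to 0), strict-upper-triangle
flattening in row-major order (R(R−1)/2 features; 19,900 at R=200,
6,670 at R=116), then a two-class Fisher criterion
[(m⁺−m)² + (m⁻−m)²] / [s²⁺ + s²⁻] per feature (sample variances; zero
denominator scores 0) with the top ⌊0.15·d⌋ kept — 1,000 of 6,670; for
19,900 the floor rule gives 2,985 (sometimes rounded to "3,000"
elsewhere; the floor convention is used consistently here).

The SSDAE/MLP compression is a compact numpy implementation: two
denoising autoencoders trained greedily (masking noise 0.2, sigmoid
encoder, linear decoder, MSE + KL-divergence sparsity on the mean
hidden activation, target 0.05, weight 10⁻³, inverted dropout 0.5,
minibatch gradient descent, lr 0.001, batch 100, 700/1000 epochs), then
a supervised MLP whose first two hidden layers start from the SSDAE
encoders (1000→600→100 + logistic head, SGD, lr 0.0005, batch 10,
dropout 0.3).  The 100-unit hidden layer is the exported
representation.  Losses, noise model and "iterations" (read as epochs)
are stated nowhere in full in the source and are config-exposed; layer
sizes are config-driven so tests exercise scaled stacks (e.g. 40→20→10)
that finish in seconds.

## Synthetic data

`gen_feature_dataset` emulates the learned representation: class 0 is
standard normal, class 1 shifts `d_inf` known dimensions by `delta`
within-class standard deviations; features are independent.  This
matches the assumptions of the KNN fitness and the Fisher filter and
gives recoverable ground truth, but it lacks correlated/redundant
features, site effects and heavy tails — passing tests show that the
machinery recovers planted univariate signal, not that it handles real
rs-fMRI covariance structure.  `gen_roi_timeseries` plants the class
difference purely in the correlation of one ROI pair (class-0 coupling
0.1, class-1 coupling 0.1 + delta), all other ROIs independent — enough
to verify that the FC stack transports correlation differences into
feature space, not a realistic BOLD noise model (no drift, motion or
autocorrelation).  Splits are stratified train/validation/test at
0.602/0.298/0.100 (the 623/308/104-of-1,035 study design) with
largest-remainder rounding per class.

## Study conditions used by tests and the acceptance script

* Sphere benchmark: 10-D sphere on the unit box [0,1]^10, N = 20,
  t_max = 300, 10 seeds.  The unit box is the domain the optimizers
  actually operate on in this package (feature-selection positions),
  and it avoids the symmetric-box degeneracy of the AOA exploitation
  operator noted above.  On it, METO and AOA drive the best solution to
  the origin corner (the multiplication operator scales the best
  solution toward zero and clipping completes the job), while ETO
  plateaus after its exploration stage — the benchmark checks elitism,
  determinism and the hybrid's added value, not general optimizer
  strength.
* Feature-recovery study: n = 600, D = 100, 10 informative features at
  1.0 σ, ρ = 0.99, K = 5, N = 20, t_max = 100, 5 seeds.  At these
  conditions the selector recovers most planted features (median recall
  ≈ 0.9) with fewer than half the features selected, while the
  all-features KNN baseline is already near the Bayes ceiling, so the
  selected-subset test accuracy lands within about one test-split
  sample of the baseline (60 test rows) and can fall on either side of
  it depending on the seed.

## Known limitations

* The printed ETO exploitation rules make late-stage refinement depend
  almost entirely on the injected AOA operators and GLS; pure ETO
  stagnates on smooth benchmarks.
* The literal-random binarization mode exists for fidelity experiments
  only; its fitness signal is pure noise with respect to the position.
* The numpy SSDAE/MLP is single-threaded and intended for the
  documented architecture at moderate input sizes; it is not a
  GPU-scale trainer.
* Multiclass labels, cross-validation protocols and alternative
  distance metrics for the KNN are out of scope.
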