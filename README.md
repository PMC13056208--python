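# metofs

Wrapper feature selection with a hybrid metaheuristic (METO) for
connectivity-based autism detection, plus the rs-fMRI feature-extraction
stack it operates on and synthetic-data generators that make the whole
workflow runnable without any neuroimaging download.

## The problem

Resting-state fMRI yields, per subject, a functional-connectivity (FC)
vector: the Pearson correlations between all pairs of brain-region (ROI)
time series, flattened from the upper triangle of the R×R correlation
matrix into R(R−1)/2 features (19,900 for a 200-ROI parcellation).  After
a Fisher-criterion filter (top 15%) and a learned compression — a stacked
sparse denoising autoencoder (SSDAE, input→1000→600) whose encoder weights
initialize a supervised MLP with a final 100-unit feature layer — each
subject is a 100-dimensional feature vector with a binary label (ASD vs.
typical control).  Even at 100 dimensions, many features are redundant or
noisy; wrapper feature selection searches for the subset that minimizes a
downstream classifier's error.

## The optimizer

The search runs over continuous positions x ∈ [0,1]^D, binarized by
BX_j = 1{x_j > 0.5}, and scored by the cost

    Fit(BX) = ρ·γ(BX) + (1−ρ)·|BX|/D,        ρ = 0.99,

where γ is the misclassification rate of a K=5 nearest-neighbor
classifier fit on the training split and evaluated on the validation
split.  Three population-based optimizers share one run contract:

* **ETO** — exponential-trigonometric optimization: dual-phase
  exploration and exploitation with exponential/trigonometric control
  coefficients (d₁/d₂, CM, α₁–α₃, c) and a constrained-exploration
  schedule that shrinks the sampling bounds around the two best
  solutions.
* **AOA** — arithmetic optimization: Division/Multiplication operators
  for exploration and Subtraction/Addition for exploitation, scheduled
  by MOA (linear) and MOP (decaying).
* **METO** — the hybrid: ETO control flow in which each solution whose
  normalized fitness share P_i = Fit_i/ΣFit falls below a random
  threshold rp takes the AOA operator of the current phase instead of
  the ETO one, plus a periodic Guided Learning Strategy (GLS) step that
  measures the dispersion of recently visited positions and either
  jumps heavy-tailed around the best solution (dispersed population) or
  restarts uniformly (collapsed population).

All formulas are implemented exactly as printed in their source
descriptions; the deliberate deviations (threshold binarization, the
d₁/d₂ ratio guard, bound handling) are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic two-class feature table (300 subjects, 30 features
of which 5 carry a 1.5 σ class shift) and run the METO wrapper selector
with 3 repetitions:

```
$ metofs simulate features --n 300 --d 30 --d-inf 5 --delta 1.5 --seed 7 --out sim
wrote sim/features.csv (300 x 30)

$ metofs select --data sim/features.csv --algorithm meto --seeds 3 --seed 0 \
      --n 20 --tmax 50 --out results_meto
               Mean    StD    Best   Worst
metric
accuracy     0.9000 0.0471  0.9333  0.8333
sensitivity  0.9778 0.0314  1.0000  0.9333
precision    0.8475 0.0493  0.8824  0.7778
fscore       0.9078 0.0420  0.9375  0.8485
auc          0.9578 0.0223  0.9889  0.9378
features    10.6667 0.4714 10.0000 11.0000
results written to results_meto
```

Each row aggregates the 3 independent runs (StD uses the population 1/n
convention; for the selected-feature count, "Best" is the smallest).
Here the selector keeps ~11 of 30 features — the 5 planted informative
ones plus a few noise features — and classifies the held-out test split
at 90% mean accuracy.  `results_meto/metadata.json` records the seeds,
the full effective configuration and the selected feature indices per
run; `metofs report --results <dir>` combines several such directories
into one comparison table.

The other stages are exposed the same way: `metofs simulate timeseries`
writes per-subject ROI time-series CSVs, and `metofs extract-features`
turns them into a learned feature table (Pearson FC → Fisher filter →
SSDAE → MLP), at sizes you choose.

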