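# Methods

## Problem and data model

The package predicts hypericin content (mg/g dry mass) of *Hypericum
perforatum* from 13 habitat and phenology descriptors. The design matrix
has a frozen column order (altitude, slope, aspect, phenology, organic
carbon, total nitrogen, phosphorus, potassium, sand, silt, clay, EC, pH);
the two ordinal variables enter as their integer codes (aspect 1–4 north
through west, phenology 1–3 vegetative through seed ripening), not
one-hot, which keeps the model input dimension at 13 and preserves the
ordered structure the sensitivity trends rely on.

Features and target are min–max scaled to [−1, 1] on **training rows
only**; constant columns map to 0. All models train and predict in scaled
space, and predictions are inverse-scaled before any metric is computed,
so every reported error is in mg/g. The 60/20/20
train/validation/test partition is a seeded uniform permutation with
floor-allocated sizes and remainders assigned train → val → test (so
n = 100 gives exactly 60/20/20). Whether the original study scaled its
inputs or randomized its split is not documented; both choices here are
the package's own, recorded in every artifact via seed and config hash.

## Synthetic generator

The original field samples are not deposited, so the pipeline runs on
synthetic data whose *marginals* are calibrated to the study's printed
per-variable summaries (mean ± SE with min/max, n = 100; SD taken as
SE × √100). Design choices:

* **Continuous marginals** — independent truncated normals with the
  printed (min, max) as hard bounds (sampled by exact truncated-normal
  draws, not clipping). Truncating a normal shifts its mean, so the
  parent location is solved by root finding such that the *truncated*
  mean equals the printed mean; the parent scale stays at the printed SD.
  Realized SDs are therefore somewhat below the printed ones (truncation
  removes tail mass) — means are matched exactly, spreads approximately.
* **Ordinal marginals** — category probabilities chosen once to match the
  printed means exactly: phenology (0.34, 0.33, 0.33) → mean 1.99; aspect
  (0.15, 0.25, 0.42, 0.18) → mean 2.63.
* **Independence** — no covariance information is printed, so covariates
  are sampled independently. This is a modelling choice, not a claim
  about the field data.
* **Response surface** — additive in the five reported active drivers,
  zero effect for the other eight: intercept 1.0631 mg/g; altitude
  3.7 × 10⁻⁵ mg/g per m (≈ 0.1 mg/g across the observed 1103–3822 m
  range); total N 0.5 mg/g per %; phenology 0.12 mg/g per stage; organic
  carbon as a two-piece linear term, 0.12 mg/g per % below the 1.5 %
  breakpoint and flat above it; aspect increments (0, 0.07, 0.12, 0.14)
  mg/g — rising north → west with a deliberately small south → west step.
  The intercept anchors the population-mean response at 1.63 mg/g. The
  output is floored at the physical 0.
* **Noise** — additive Gaussian, SD 0.05 mg/g, clipped at 0. With the
  surface's signal SD of ≈ 0.13 mg/g this caps attainable R² at ≈ 0.87,
  putting a well-fit model's test R² in a realistic 0.8–0.95 band.

What passing tests on this generator do **not** show: recovery of the
field data's joint distribution (correlated soils, transect
autocorrelation, interactions), robustness to measurement error in the
covariates, or the study's exact headline metric values — those were
computed on the undeposited field samples and are not reproducible from
the publication alone.

## Models

**MLP.** One logsig hidden layer, linear output, biases in both layers.
Initialization is seeded uniform on [−0.5, 0.5]. The default trainer is
Levenberg–Marquardt on the per-sample residual Jacobian: solve
(JᵀJ + λI)Δ = −Jᵀr, accept only SSE-decreasing steps (λ ÷ 10 on success,
× 10 on rejection, abort at λ > 10¹⁰), which makes the accepted-loss
trace nonincreasing and interpolates between Gauss–Newton and gradient
descent. Plain full-batch backprop (learning rate γ, default 0.05) is
kept both as an alternative trainer and as the analytically
differentiated reference for gradient tests. Both trainers early-stop on
validation MSE (patience 25) and return the best-validation parameters.
The preset hidden size is 26; `init_mlp`/`fit_mlp` accept any size for
the trial-and-error search the preset came from.

**RBF network.** Shared-spread Gaussian basis; centres picked by greedy
forward selection from the training points (the candidate that most
reduces training SSE joins the network), output weights + single bias
refit by `lstsq` after each addition, best-validation configuration kept.
A rank-deficient design falls back to a ridge-stabilized solve (λ=1e−10)
with a warning; an underdetermined-but-clean system (m + 1 > n) is left
to the minimum-norm `lstsq` solution. A k-means placement strategy is
available as a flag. The preset (48 neurons, spread 50) is stored as
printed; note that on [−1, 1]-scaled features a spread of 50 makes all
activations ≈ 1 and the network nearly collinear — the study does not say
what scaling its spread refers to, so the value is honoured, not
reinterpreted.

**ε-SVR.** The dual of ½‖w‖² + CΣξ with ε-insensitive loss is solved by
a from-scratch SMO over the 2n box variables (α⁺, α⁻) with Σ(α⁺−α⁻) = 0:
maximal-violating-pair selection for the first index, second-order
(maximal one-pair gain) selection for the partner, canonical two-variable
closed-form update, incremental gradient maintenance with a periodic
exact refresh to flush rounding drift. Stopping is a KKT gap below `tol`
(default 1e−8); on very ill-conditioned kernels the attainable gap is
floating-point-limited, and the solver raises rather than silently
returning a poor solution. The bias is averaged over margin-interior
support vectors, falling back to the midpoint of the KKT-feasible
interval. ε and C act on the scaled target — the preset ε = 0.0002 is
only meaningful on a normalized scale. γ defaults to 1/13 (the study
prints none).

## Metrics and selection

MSE, RMSE (= √MSE identically), MAE, and two R² forms, always on mg/g:
`r2_ratio` = Σ(ŷ−ȳ)²/Σ(y−ȳ)² with ȳ the observed-target mean of the
evaluated partition, and the conventional `r2` = 1 − SSE/SST. The ratio
form is the study's comparison statistic and drives selection (highest
test value wins; ties → lower test RMSE → model id), but it is not
bounded by 1 for biased predictors — e.g. y = [0, 2], ŷ = [0, 4] gives
r2_ratio = 5 — which is why the conventional form is always reported
alongside. Zero target variance raises rather than returning a value.

## Sensitivity analysis

One-at-a-time: each variable sweeps k = 21 evenly spaced values over
mean ± 1 SD (width multiplier configurable), clipped to the physical
bounds; ordinals sweep all codes. All other variables sit at their
training means (ordinals: nearest valid code — e.g. a mean aspect of 2.6
pins aspect at 3). The raw sensitivity is the population SD of the model
predictions over the grid (mg/g); normalized scores divide by the largest
raw SD, so scores lie in [0, 1] with the top variable at exactly 1 (an
all-zero profile scores 0 with a warning). Response curves export each
grid with its predictions and a monotonicity tag. Statistics are always
computed from the training partition so the analysis describes the
fitted model, not the held-out data.

## Reproducibility and problem sizes

Every stochastic step (generation, split, initialization, k-means) uses
an explicit seed; CSV artifacts are written with fixed float formatting,
so a rerun from a config snapshot is byte-identical. Prediction paths use
row-wise reductions rather than BLAS matvecs where duplicate input rows
must yield bit-identical outputs. The test suite uses desk-scale problem
sizes chosen for statistical adequacy: 10,000 draws for marginal
calibration checks (SE of the mean ≈ SD/100), 2,000 samples for the
sensitivity-recovery experiment (the altitude partial effect, ≈ 0.016
mg/g grid SD, must be resolvable above the 0.05 mg/g noise), 300/200
train/test for teacher–student recovery, and n ≤ 30 for the
QP-oracle comparisons.

## Known limitations

* The generator's response surface is additive; it cannot probe model
  behaviour under interactions or correlated covariates.
* The printed spread/ε/C presets are honoured verbatim although the
  scaling they originally referred to is unknown; their effective
  geometry here may differ from the original toolbox fits.
* `r2_ratio`-based selection can prefer a biased high-variance predictor
  over a better-calibrated one (it is kept because it is the study's
  rule); consult the conventional `r2` column when it matters.
* The SMO solver targets dense problems at field-study scale (tens to
  thousands of samples); it has no kernel cache or shrinking and is not
  meant for large n.
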