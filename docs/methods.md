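# Methods

## Scope and model

pdxsig links two preclinical assays of the same drug: a cell-line viability
screen summarized per line by the relative half-maximal inhibitory
concentration (rIC50), and a xenograft efficacy screen summarized per tumor
model by an ordinal response class derived from tumor-volume trajectories.
The working hypothesis is linear: basal log-scale mRNA abundance x predicts
log₁₀ rIC50 as y = β₀ + Σ xⱼβⱼ + ε, with most βⱼ exactly zero. The fitted
linear combination, evaluated on a new cohort's expression, is a composite
sensitivity score whose discriminatory power against observed in vivo
outcomes is the validation criterion.

rIC50 is stored in molar units and modeled on the log base-10 scale; the
base only rescales coefficients and was chosen for readability of
concentration ranges (−9 ≈ nM).

## Response criteria

Relative tumor volume RTV(t) = V(t)/V(0). Over a study window (default 42
days), with minRTV the trajectory minimum and finalRTV the value at study
end, and a measurable-tumor threshold (default 100 mm³):

| class | rule | score |
|---|---|---|
| MCR | some post-baseline volume < threshold, final volume < threshold | 10 |
| CR  | some post-baseline volume < threshold, final volume ≥ threshold | 8 |
| PR  | no CR event, minRTV ≤ 0.5 | 6 |
| SD  | minRTV > 0.5, finalRTV < 1.25 | 4 |
| PD2 | minRTV > 0.5, finalRTV ≥ 1.25, EFS > 1.5 × control median | 2 |
| PD1 | as PD2 without the growth delay (or no control arm) | 0 |

Event-free survival (EFS) is the linearly interpolated time to RTV ≥ 4
(censored at the last observation; a censored EFS counts as an arbitrarily
long delay in the PD2 comparison). The published scale fixes only the
endpoints (PD1 = 0, MCR = 10) and the median-based group score; the interior
thresholds above follow common solid-tumor screening convention and are all
configurable. A group's score is the median of its animals' scores, with an
even-count half-step median mapped to the *lower* adjacent class so
aggregation never upgrades activity. ORR percentages round half away from
zero to one decimal.

Classification is total and deterministic, and uniformly shrinking all
post-baseline volumes can never move a trajectory toward PD1 (property
tested on randomized trajectories).

## Signature pipeline

Order of operations, with the rationale for what is inside vs outside
cross-validation:

1. **Global pre-processing** (target-independent, done once): per-feature
   z-scoring (n−1 sd; constant features dropped), z-scoring of y, and
   removal of outputs inconsistent with a normal curve by a single-pass
   robust rule |y − median| / (1.4826·MAD) > 2.5, capped at 20% of samples.
   Censored rIC50 values (no inhibition at the maximum dose) enter at their
   censoring value by default — they carry real resistance information —
   with a flag to exclude them.
2. **Univariate screen** (target-dependent, therefore nested): Pearson
   correlation of each feature with y, kept when the *uncorrected* p is
   below `alpha_local`. The rate is deliberately liberal: the realized
   type-I error is much larger, and that is harmless because the penalized
   fit removes uninformative inputs. Default `alpha_local = 0.10`, chosen so
   the screen has roughly 50% power at the smallest effect the synthetic
   generator plants (marginal r ≈ 0.12 at n = 200); at stricter rates the
   screen, not the elastic net, becomes the recall bottleneck.
3. **Cross-validation**: one fold assignment drawn from the seed and reused
   across the whole (α, λ) surface. Within each training fold the z-scoring
   and the screen are re-fit, so feature selection is included in the
   estimated prediction error; held-out samples are transformed with the
   training fold's parameters. The λ grid per α is anchored at the full-data
   λmax = maxⱼ |(1/n) zⱼᵀ(y−ȳ)|/α so errors are comparable across folds.
   Selection is the minimum mean CV MSE, ties broken toward larger λ
   (sparser), then larger α. α grid {0.1, …, 1.0}; α = 0 is excluded
   because λmax is undefined there.
4. **Final fit**: the screen on the full data defines the candidate set; the
   solver warm-starts down the path to the selected (α, λ).

### Solver

Cyclic coordinate descent on the objective
(1/2n)‖y − β₀ − Zβ‖² + λΣⱼ[(1−α)βⱼ²/2 + α|βⱼ|], with update
βⱼ ← S((1/n)zⱼᵀr + vⱼβⱼ, λα)/(vⱼ + λ(1−α)) where vⱼ = (1/n)zⱼᵀzⱼ and S is
the soft-threshold operator. Because features are standardized with the n−1
convention while the loss uses 1/n, vⱼ = (n−1)/n rather than 1; the update
uses the exact vⱼ so the fixed point is the true minimizer. Convergence is
max |Δβⱼ| < tol (default 1e-6; 1e-4 inside CV where only the MSE ranking
matters); an active-set strategy alternates full sweeps with cycles over the
nonzero set. KKT residuals are checked in the test suite on every fit, and
the solver's objective agrees with an independent reference minimizer to
1e-6 on randomized instances. Intercepts are handled by centering, so the
null model at λ ≥ λmax returns β₀ = ȳ exactly.

The λ path is log-spaced, 100 values down to 0.01·λmax by default — the
conventional floor when candidates outnumber samples; solutions below that
floor are dense, slow to converge, and never selected by CV in calibration
runs.

### Translation

Training (cell lines) and validation (xenografts) are different cohorts and
potentially different platforms, so xenograft expression is z-scored within
the xenograft cohort; the sensitivity score is the negated prediction
(larger = predicted sensitive). Signature features missing from the new
platform contribute zero, with an error when more than 10% of the nonzero
features are absent. AUC uses midrank tie handling, making the trapezoidal
curve area and the pairwise Mann–Whitney count identical; its null is a
seeded label-permutation sample with the add-one p estimator.

## Screening statistics

- Signal-to-noise θ = (μₓ−μᵧ)/(σₓ+σᵧ) with n−1 standard deviations;
  permutation p-values are two-sided on |θ| with the add-one rule (the
  smallest attainable p is 1/(n_perm+1)).
- Welch's t with the Welch–Satterthwaite df; the fully degenerate case
  (both groups constant and equal) returns t = 0, p = 1.
- Storey q-values: π₀(λ) = #{p>λ}/(m(1−λ)) on λ = 0.05…0.95, cubic
  polynomial fit evaluated at λ = 0.95, clipped to (0, 1]; q is the
  step-down minimum of π₀·m·p(ⱼ)/j. Below 100 tests the smoother is
  unreliable and π₀ falls back to 1, which makes the q-values exactly
  Benjamini–Hochberg.
- Enrichment is the inclusive hypergeometric right tail, identical to the
  one-sided Fisher exact test on the 2×2 table.
- CNV–expression ranking uses signed r descending (the biological claim is
  positive dosage coupling), with an |r| option.
- "Upstream" for lincRNA cis-links is strand-aware relative to the gene's
  TSS, distance measured TSS to nearest interval edge, default window
  100 kb, and requires a significant expression correlation.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, with
ground truth for recovery testing. Defaults define the study conditions used
throughout the tests.

- **Expression**: 3,000 coding + 500 lincRNA features in blocks of 10 with
  within-block correlation 0.5 via a shared latent factor; feature means
  ~N(8, 1.5) and scales U(0.5, 1.5) on the log2 scale, shared between the
  cell-line and xenograft cohorts (same platform), samples independent.
- **Signature**: k = 10 features planted in distinct blocks, effects
  U(0.3, 1.0) with random sign on the standardized scale; noise sd set from
  the realized signal sd to hit a target R² (default 0.7); the realized
  squared correlation stays within ±0.1 of target on average across seeds.
- **Transporter (optional)**: one extra feature expressed as a two-mode
  Gaussian mixture (prevalence 0.3, mode separation 2 sd) whose high state
  adds +2 log₁₀ units of resistance. The effect on y is a state shift, not a
  linear function of expression — the documented blind spot of a linear
  screen. At the default 22-line training size the pipeline selects it in
  fewer than half the seeds despite the large marginal shift; the regression
  test asserts exactly that.
- **Growth model**: V(t) = V₀·exp(g·t − d·min(t, T)) per animal, with
  per-animal lognormal jitter on baseline (median 300 mm³, sd 0.3), growth
  rate (doubling time 7 d, sd 0.3), and effective treatment duration
  (median 36 d of the 42-d window, sd 0.2); multiplicative lognormal
  measurement noise (sd 0.12) at twice-weekly observations, baseline
  included. Kill rate d = d_max·logistic(−z) with d_max twice the growth
  rate and z the cohort-standardized resistance score. Four treated and four
  control animals per model; controls share the growth model with d = 0 and
  provide the median EFS for the PD1/PD2 split.

  These constants were calibrated jointly, once, so that (i) all six
  response classes appear in essentially every 40-model cohort and (ii) the
  class boundary is informative about the signature score (a true-score
  classifier reaches AUC ≈ 0.97). A fixed single-animal design cannot do
  both: the CR class requires regrowth after treatment, the SD class
  requires near-stasis to study end, and with one animal per arm the
  per-animal growth jitter that populates the intermediate classes also
  swamps the score–outcome coupling. Median aggregation over four animals
  resolves the conflict, and matches how screening consortia actually score
  groups.
- **CNV**: coupled genes follow ρ·z_expr + √(1−ρ²)·noise (default ρ = 0.9
  for 10 genes) on a 0.5 log2 scale; others are independent noise.
- All randomness derives from a single seed through named substreams;
  every output is bit-reproducible.

### What the generator does not emulate

Probe-level artifacts, batch and normalization effects, heavy-tailed or
skewed expression, platform differences between training and validation
cohorts (beyond independent standardization), lineage structure among
models, censoring of rIC50 at dose limits (off by default), and
pharmacokinetics (dose schedules, exposure differences between mouse and
human). Passing recovery and AUC tests on these cohorts therefore
demonstrates correctness of the machinery under the model's own
assumptions — not expected field performance on real arrays, where
training sizes near 22 lines make recovery unstable (the small-n regime is
exercised deliberately at the default cohort size).

## Problem sizes in the test suite

Recovery and translation properties are measured on 20 seeded replicates at
200 training cell lines, p = 3,500, k = 10, R² = 0.7, and 40 xenograft
models — the size at which nested-CV recovery is stable — with the same
cohorts reused for the pure-noise (permuted outcome) null. q-value
calibration uses 100 replicates of m = 5,000 Welch tests (40 replicates for
the planted-shift FDR check). Solver and AUC identities run on dozens of
small randomized instances against scikit-learn and exact pairwise counts.

## Known limitations

- The elastic-net candidate set is gated by the univariate screen; effects
  below the screen's detection limit at the given n cannot be recovered
  regardless of the penalty, and non-linear or subpopulation-restricted
  patterns (the transporter) are invisible to it by design.
- Storey's smoother is evaluated at λ = 0.95 with a cubic fit; with few
  tests or very non-uniform nulls the π₀ estimate is noisy, hence the BH
  fallback below 100 tests.
- Group classes from small animal groups inherit median jitter; EFS
  interpolation assumes RTV is locally linear between observations.
- The CV surface is searched on a fixed α grid; λ is continuous along the
  path but α is not interpolated.
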