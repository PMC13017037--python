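# Methods

This note documents the models implemented in `traitnet`, the assumptions
behind them, the defaults that matter, and the design choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Trait scores

Fourteen per-subject indices are derived from raw trial records:

| trait | definition | units |
|---|---|---|
| growth | (final − initial length)/initial × 100 | % |
| basal_metabolism | basal ventilation / body weight | bpm/g |
| stress_metabolism | (stress − basal ventilation)/basal × 100 | % |
| activity | open-field distance moved (mean of 2 trials) | cm |
| thigmotaxis | time in outer band / total × 100 | % |
| scototaxis | time in dark half / total × 100 | % |
| sociability | time near mirror / (total − center) × 100 | % |
| motor/visual_lat_rel | (cw − ccw)/(cw + ccw) × 100 | % |
| motor/visual_lat_abs | \|relative index\| | % |
| spatial_learning | days to criterion, learning phase | days |
| flexibility | −(reversal − learning days)/learning days | index |
| memory | −(memory − reversal days)/reversal days | index |

Repeated assays (behavior, lateralization) are scored per trial and
averaged over the two trials; a control setting scores lateralization from
the first trial only, and a raw-variable control keeps stress-condition
ventilation (bpm) and reversal days in place of the two derived indices.
Note that the absolute-index identity `abs = |rel|` holds at the trial
level; after averaging two trials, mean(|r₁|, |r₂|) ≥ |mean(r₁, r₂)|, so
the two table columns are related but not redundant.

**Learning criterion.** A phase is solved on the first day *d* ≥ 2 whose
trailing two-day window holds ≥ 10 correct choices of 12. Windows are
*overlapping* consecutive-day pairs, not aligned two-day blocks. This
reading is self-consistent with the package's own chance simulation and
exact oracle (below); the aligned-block reading produces a substantially
lower chance rate and is not implemented. Undefined scores (zero
denominators, missing phases) become missing cells rather than errors, so
they flow into the imputation stage.

Chance expectations for the zone scores derive from apparatus geometry:
for a square arena of side L with an edge band of width w the thigmotaxis
chance level is (L² − (L − 2w)²)/L² × 100 ≈ 40% at L = 40 cm, w = 4.5 cm;
half-split apparatuses have a 50% chance level; the relative
lateralization chance expectation is 0.

## Chance-performance null

A random chooser's daily correct count is Binomial(6, ½). The Monte-Carlo
null draws `n_replicates` cohorts of `n_subjects` such choosers over
`n_days`, applies the same criterion code path used for real cohorts, and
records the per-replicate percentage reaching criterion. The p-value for
an observed number of learners uses the add-one convention
(1 + #{replicates ≥ observed})/(n_replicates + 1), which cannot return 0
from a finite run.

An exact companion computes P(criterion within n days) by dynamic
programming over the previous day's count (states 0…6), in rational
arithmetic: P = 79/4096 at n = 2 (the Binomial(12, ½) upper tail at 10)
and is strictly increasing in the horizon. The test suite requires the
Monte-Carlo mean to sit within three standard errors of this oracle.

## Univariate statistics

Standard tests are delegated to scipy: one-sample and paired t
(two-sided; the first-day memory binomial is one-sided "greater"), Levene
in the Brown–Forsythe median-centered form (robust default; the centering
is otherwise unspecified), Spearman with average ranks, exact binomial
with Clopper–Pearson intervals. Missing values are dropped pairwise —
imputation is reserved for the network stage.

**Repeatability** is the intraclass correlation of a one-way
random-intercept Gaussian model, R = σ²ₐ/(σ²ₐ + σ²ₑ). The point estimate
uses ANOVA variance components (Searle's n₀ for unbalanced designs,
negative components truncated at 0); the CI is a percentile parametric
bootstrap (default 1,000 draws) simulating from the fitted components with
the observed group sizes; the p-value is a likelihood-ratio test of
σ²ₐ = 0 against the ½χ²₀ + ½χ²₁ mixture, with the marginal ML likelihood
evaluated in closed form through the compound-symmetry block structure.
The test suite verifies ≥ 90% CI coverage at true ICC 0.6 in the 24 × 2
study design.

**Learning curve.** Daily error counts are modeled as grouped binomial
with logit(p) = β₀ + β₁·day + uᵢ, uᵢ ~ N(0, σ²). No frequentist binomial
mixed-model routine exists in the Python scientific stack, so the marginal
likelihood is maximized directly with Gauss–Hermite quadrature (25 nodes,
Nelder–Mead over (β₀, β₁, log σ)); the day effect is a 1-df likelihood
ratio. Parameter recovery (slope within ±0.15 of a planted −0.4 at 200
subjects) is asserted in the tests. All-correct or all-error input is
flagged as separation and returned without estimates.

## Multiple imputation

Chained equations with predictive mean matching: each incomplete column is
regressed on all others (intercept + linear terms, 10⁻⁸ ridge for
stability); the residual variance receives a scaled inverse-χ² draw and
the coefficients a normal draw; each missing cell is filled with the
observed value of a donor sampled uniformly from the 5 nearest predicted
means (type-1 matching: observed predictions use the least-squares
coefficients, missing predictions the drawn ones). Defaults m = 5 chains,
maxit = 50 sweeps, donors = 5 (the canonical PMM donor count); the initial
fill is a random draw from each column's observed values. Observed cells
are never modified, and every imputed value is by construction an observed
value of its column.

Downstream pooling: the Spearman matrix is computed per completed table
and averaged on the Fisher-z scale (`pooling="first"` uses only the first
table). Averaging is the least-surprising default where no pooling rule is
canonical; it is exposed as a switch.

## Network estimation

Networks are estimated on the Spearman matrix (pairwise-complete; repaired
to the nearest positive-semidefinite correlation by eigenvalue clipping
when pairwise deletion breaks PSD, with a warning). Two estimators sit
behind one switch:

* `correlation` — edge weights are the Spearman coefficients (zero
  diagonal);
* `ebicglasso` (default) — graphical lasso over a log-spaced penalty grid
  (100 values, smallest = 0.01 × max |off-diagonal|), model selected by
  extended BIC with γ = 0.5; edge weights are the standardized negative
  precision off-diagonals (partial correlations). At vanishing penalty
  this reproduces the unregularized partial correlations (verified to
  1e-6 in the tests).

**Centrality.** Strength = Σ|w|, expected influence = Σw (one-step),
eigenvector = principal eigenvector of |W| scaled to max 1. Eigenvector
centrality is sign-blind, which is exactly why expected influence is
carried separately: negative edges cancel in it but not in strength or
eigenvector. An empty network reports zero centralities with a warning.

**Edge stability.** Subjects are resampled with replacement (default
1,000 resamples), the network re-estimated per resample, and each edge
summarized by its percentile 95% interval; edges whose interval excludes
zero form the significance mask — the unweighted network. Resamples where
a column degenerates to a constant leave that column's edges out of the
affected intervals. `selection="refit"` (default) reruns EBIC penalty
selection inside every resample; `selection="fixed"` selects the penalty
once on the full sample and reuses it — a large speedup used in the
package's simulation studies, at the cost of ignoring selection
variability.

**CS-coefficient.** For each drop proportion in a 0.05…0.75 grid (step
0.05), subjects are subsampled without replacement, the chosen centrality
recomputed and correlated (Pearson) with the full-sample centrality. The
CS-coefficient is the largest drop proportion in the contiguous run from
the smallest level at which ≥ 95% of resamples correlate ≥ 0.7; scanning
stops at the first failing level, since recoveries past a failure are
noise. Resamples with an undefined metric (e.g. an empty subset network)
count as below threshold. CS < 0.25 flags the metric as unstable.

## Synthetic cohorts

The generator emulates the study's raw-record schema with a known latent
structure: one N(0, Σ) draw per subject over the 14 trait dimensions
(Σ configurable, identity by default), mapped monotonically to
observables — logistic squashing to time fractions for zone scores and
lateralization magnitude, affine maps clipped at zero for distances and
rates, allometric weight from length. Monotone maps preserve ranks, so
Spearman statistics computed downstream recover the planted structure (for
a bivariate normal, Spearman ρₛ = (6/π)·asin(ρ/2), a ≤ 0.02 attenuation —
the tests assert recovery within ±0.05 at n = 5,000). Default trait
locations and spreads are plausible population values for juvenile tench
(e.g. thigmotaxis ≈ 78%, basal ventilation ≈ 84.5 bpm/g, stress response
≈ 103%).

Repeated assays draw per-trial latents with correlation `trial_icc`
(default 0.7, typical of repeatable behavioral scores) around the subject
latent; `trial_icc=1` disables trial noise so the scored traits are
strictly monotone in their latents — the setting used in the
parameter-recovery studies, where the planted structure is defined at the
trait level.

Maze phases set each subject's daily P(correct) to a logistic curve
expit(a + s·d) whose slope s is log-normal in the subject's latent for
that phase (calibrated so the default cohort's days-to-criterion land near
the nominal targets: learning ≈ 5 days starting at chance, memory ≈ 3 days
starting above chance); daily choices are Bernoulli draws and the sequence
truncates on the criterion day (or a 20-day cap). Because flexibility and
memory indices are deterministic contrasts of the shared days-to-criterion
values, the scored table has *structural* partial correlations among the
three maze traits even under independent latents; planted-edge recovery
studies therefore plant edges among the nine directly-transmitted
continuous traits.

Missingness mimics dropout: whole assay blocks are removed per subject
(never the first-timepoint morphometrics), each with probability q solving
16q − 2q² = 14·rate, which makes the expected missing-cell fraction of the
24 × 14 trait table exactly `rate` (default 6/336 ≈ 1.8%) including the
cascade of missing maze phases into the derived indices. Blocks drop
independently rather than in a strictly sequential withdrawal pattern; the
expectation calibration and the protected baseline block are what the
downstream analyses are sensitive to.

**What the generator does not emulate:** video-tracking noise, invalid
trials (> 20 min, assumed excluded upstream), within-day trial-order
effects, tank or arena geometry beyond zone-time fractions, and
missingness that depends on the unobserved values (MNAR). Passing tests
therefore certify the statistical machinery, not the measurement process
of a real cohort.

## Problem sizes and tolerances

The chance simulation uses the study conditions exactly (24 subjects,
8 days, 10,000 replicates; < 1 s vectorized). Simulation-based tests scale
the bootstrap machinery to keep the suite fast while leaving signatures at
the canonical defaults (1,000 resamples, 100-point penalty grids):
recovery tests use 250 bootstrap resamples with a 30-point grid and
fixed-penalty resampling; pipeline determinism checks run miniature
configurations. Tolerances follow the statistic's own sampling noise:
3 Monte-Carlo standard errors against the exact oracle, ±0.05 on rank
correlations at n = 5,000, ±0.2 on post-imputation correlation bias in a
24-row table, ≥ 90% frequency criteria over 50–100 seed replications.

## Known limitations

* The graphical lasso backend (scikit-learn) occasionally stops at its
  iteration cap for near-zero penalties; the residual dual gap is orders
  of magnitude below the EBIC differences involved, so model selection is
  unaffected.
* The repeatability bootstrap is percentile-based and mildly anticonservative
  at very small subject counts, as percentile intervals generally are.
* The chained-equations model is linear-Gaussian per column; strongly
  nonlinear trait relations would bias imputations (PMM's donor mechanism
  limits, but does not remove, this).
* CS-coefficients are reported on the same grid as the canonical
  case-dropping scheme; values between grid points are not interpolated.
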