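# traitnet

Trait covariance networks for wild-animal cohorts.

Behavioral ecologists increasingly ask not whether single traits vary among
individuals, but how cognitive, behavioral, physiological and life-history
traits *covary* — because covariation constrains how selection can act on any
one of them. `traitnet` implements the full analysis chain behind such
studies, modeled on a cohort of wild juvenile tench (*Tinca tinca*) assayed
for 14 traits: growth, basal and stress metabolism (opercular ventilation),
open-field activity and thigmotaxis, scototaxis, sociability, motor and
visual lateralization (relative and absolute), and three criterion-based
T-maze measures (spatial learning, cognitive flexibility, memory).

The package provides:

* **trait scoring** — every derived index from raw trial records, e.g.
  growth = (L₁ − L₀)/L₀ × 100, relative lateralization
  = (t꜀ᵥᵥ − t꜀꜀ᵥᵥ)/(t꜀ᵥᵥ + t꜀꜀ᵥᵥ) × 100, and days-to-criterion for the
  maze (first day *d* ≥ 2 with ≥ 10 correct of 12 over days *d−1, d*);
* **a Monte-Carlo chance null** for criterion-based learning — replicate
  cohorts of Binomial(6, ½) choosers — plus an exact dynamic-programming
  oracle for the same probability;
* **univariate statistics** — t-tests, Brown–Forsythe Levene, exact
  binomial, Spearman correlations, intraclass-correlation repeatability
  with parametric bootstrap, and a grouped-binomial learning-curve GLMM;
* **multiple imputation** by chained equations with predictive mean
  matching (m = 5, 50 iterations by default);
* **network inference** — regularized partial correlations (graphical
  lasso selected by extended BIC, γ = 0.5) or the raw Spearman matrix;
  strength, eigenvector and expected-influence centrality; edge-weight
  bootstrap defining the significant (unweighted) edge set; and the
  case-dropping correlation-stability (CS) coefficient (r = 0.7, 95%
  certainty, 0.25 reliability rule);
* **a synthetic-cohort generator** with a configurable latent trait
  correlation matrix, so every stage is testable and parameter recovery can
  be asserted end to end.

## Worked example

```python
import traitnet as tn

# a 24-subject cohort with the study's missing-data rate
cohort = tn.generate_cohort(tn.CohortConfig(seed=3))
table = tn.build_trait_table(cohort)        # subjects x 14 trait scores

# is criterion-based learning explainable by chance in <= 8 days?
null = tn.simulate_chance_experiment(24, 8, n_replicates=10_000, seed=1)
print(f"{null.mean_percentage:.2f} +/- {null.sd_percentage:.2f}%")
print("p(24/24 learners) =", tn.pvalue_observed(null, 24))

# impute, estimate the regularized partial-correlation network, rank nodes
imputed = tn.pmm_impute(table[tn.NETWORK_TRAITS_12], seed=500)
net = tn.CovarianceNetwork().fit(imputed)
print(tn.centrality(net).sort_values("expected_influence").tail(3))
```

Output:

```
11.38 +/- 6.49%
p(24/24 learners) = 9.999000099990002e-05
                  strength  eigenvector  expected_influence
node
spatial_learning       0.0          0.0                 0.0
flexibility            0.0          0.0                 0.0
memory                 0.0          0.0                 0.0
```

Under chance alone only ~11% of random choosers reach the learning
criterion within 8 days, so a cohort in which all 24 subjects learn is far
outside the null (p < 10⁻⁴). On this particular synthetic cohort (drawn
with an identity latent correlation) the EBIC-selected network is empty —
the expected answer when no trait covariance is planted; planting a latent
correlation structure produces the corresponding edges, which is what the
test suite asserts quantitatively.

The same pipeline is scriptable from the shell:

```sh
traitnet run-all --seed 1 --out runs/demo          # full pipeline
traitnet chance-sim --n-subjects 24 --n-days 8 --observed 24 --out runs/chance
```

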