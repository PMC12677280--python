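# amcsuite

Data-driven categorization of zero-inflated predictors for case-control
association analysis.

Patient-level NLP features extracted from clinical notes — summed term
frequencies per patient — are awkward predictors: most patients score
exactly zero on most concepts, the positive part is strongly right-skewed,
and excess risk concentrates in the upper tail. Linear models on the raw
values are misspecified, and quartile binning collapses the entire tail
into one bin. This package implements **adaptive-mixture-categorization
(AMC)**, a supervised-binning-free, variance-driven discretization that
finds thresholds adapted to the mixture structure of each variable, and a
battery of association tests to compare it against the conventional
alternatives on a binary (e.g. case-control) outcome.

## The method

For a variable x of length n split into k ordered categories by thresholds
t₁ < … < t_{k−1} (inclusive upper bounds: category i is t_{i−1} < x ≤ tᵢ),
the loss of the categorization is the reciprocal of the one-way ANOVA F
statistic,

    L = (WSS / (n − k)) / (BSS / (k − 1)) = 1 / F,

the ratio of within-category to between-category variation. AMC searches
greedily: the k = 2 step picks the single best cut; each later step adds
one cut holding the earlier ones fixed. Candidate cuts are restricted to
the lower edges of the largest *gaps* (differences between adjacent
distinct sorted values; 1000 by default), which leaves the solution
essentially unchanged while making each sweep linear in the number of
candidates. The number of categories is the k ≤ 10 maximising the F-test
−log₁₀ p along the path — the loss itself always improves with k, but the
F test pays for degrees of freedom. Finally, sparse categories (< 20
subjects) merge into their left neighbour, so the heavy right tail cannot
produce unstable micro-categories.

The fitted categories are then tested against the outcome five ways:
chi-square on AMC categories (`amc_chi`) and quartile categories
(`quantile_chi`), with phi = √(χ²/N) as effect size; logistic-regression
linear-trend tests on the integer category codes (`amc_linear`,
`quantile_linear`) and on the raw values (`untransformed_linear`), with
Cohen's d. All p-values are carried as −log₁₀ p computed on the log scale,
since these tests routinely reach p ≈ 10⁻²⁰⁰.

Because the source EHR cohort is not public, the package ships (a) the 20
published per-category count tables from the emulated study (4990 suicide
cases vs 20,352 matched controls), usable as exact fixtures, and (b) a
synthetic generator of matched case-control cohorts with zero-inflated
log-normal predictors and a logistic tail-risk effect, on which every
pipeline stage runs end to end.

## Worked example

```python
import numpy as np
from amcsuite import (SimConfig, generate_cohort, amc_fit, quantile_fit,
                      assign, contingency, chi_square, phi)

cohort = generate_cohort(SimConfig(n_cases=500, control_ratio=4,
                                   n_predictors=10, seed=42))
x = cohort.predictor("X001")
cat = amc_fit(x)
print(cat.thresholds)   # (0.876, 1.805, 2.971, 4.811, 7.109)
print(cat.category_counts)  # (1892, 261, 112, 107, 61, 67)

table = contingency(assign(x, cat), cohort.outcome)
stat, df, mlp = chi_square(table)
print(round(mlp, 2), round(phi(table), 3))  # 19.07  0.199
```

The first category absorbs the zero-plus-small mass and the remaining
cuts slice the tail; the chi-square −log₁₀ p of 19.07 compares with 8.67
for quartile binning of the same predictor — the tail categories carry
the signal.

The same comparison at full scale (`analysis/03_full_cohort_associations.py`,
4990 cases / 19,960 controls, 50 predictors) prints:

```
method                mean_minus_log10_p  mean_effect_size
amc_linear                        40.369             0.219
amc_chi                           39.740             0.089
quantile_chi                      31.955             0.078
quantile_linear                   26.885             0.172
untransformed_linear              22.879             0.181
```

(effect sizes are phi for the chi-square rows, Cohen's d for the others).

## Analysis scripts

Numbered drivers under `analysis/` re-run the full study on the emulated
cohort and write their tables under `results/`:

1. `01_reanalyze_published_tables.py` — chi-square, phi and tail risk
   profiles recomputed from the packaged published count tables.
2. `02_simulate_cohort.py` — the 24,950-subject synthetic cohort.
3. `03_full_cohort_associations.py` — the five-method battery.
4. `04_dictionary_comparison.py` — per-dictionary aggregation and
   category-wise risk profiles for the top predictors.
5. `05_subsample_sensitivity.py` — 100 undersampling iterations at
   500/2000 and 1000/4000; AMC wins 84–91% of comparisons with ~26%
   larger mean phi.

A `amcsuite` CLI (`simulate`, `categorize`, `associate`, `compare`,
`subsample`) exposes the same stages on TSV files.

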