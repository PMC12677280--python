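# Methods

## The AMC model

AMC treats a continuous predictor as an implicit mixture — a point mass at
zero plus one or more skewed positive components — and discretises it by
maximising retained variance. A categorization into k ordered categories
with inclusive upper-bound thresholds is scored by the one-way ANOVA
decomposition of the predictor over its own categories: loss = 1/F, the
df-scaled ratio of within- to between-category sums of squares. The
search is a linear (greedy) one: the first cut minimises the loss at
k = 2; each later cut is added with earlier cuts frozen. The selected k
maximises the F-test −log₁₀ p along the greedy path; ties prefer the
smaller k. Note the selection uses the predictor alone — the outcome never
enters the binning, so AMC is not supervised binning and does not inflate
downstream association tests by peeking at case status.

Assumptions worth stating: (i) the informative structure is captured by
location separation between contiguous blocks of the sorted values —
multimodal structure interleaved on the value axis is invisible to any
threshold method; (ii) the F statistic is used descriptively, as a
variance-ratio score, not as an inference about Gaussian groups; (iii)
categories are meaningful only down to the occupancy floor (20 subjects by
default), below which they merge leftward (the leftmost category, having
no left neighbour, merges right).

### Search mechanics and numerics

* Candidate cuts are the lower edges of the largest gaps between adjacent
  distinct sorted values (default cap 1000, `max_gap_candidates`). Gaps
  are global order statistics, so the candidate set is computed once per
  predictor and consumed across k-steps; a consumed candidate is removed.
  With the cap at or above the number of distinct gaps the search is
  exactly the unrestricted one (tested).
* Because thresholds live on the value axis, every category is a
  contiguous block of the sorted sample; each candidate evaluation is two
  prefix-sum lookups per category, so a greedy sweep costs
  O(#candidates × k) rather than O(#candidates × n). A full fit at
  n ≈ 25,000 takes ~5 ms.
* Ties between candidate cuts (equal between-SS within 1e−12 relative)
  break toward the smaller threshold; k-ties toward the smaller k.
* `within_ss` below 1e−12 of the total SS is treated as zero: the F
  statistic is flagged infinite, the loss is 0, and the search stops
  (no further split can improve a perfect separation).
* p-values for F, chi-square and Wald z are computed on the log scale
  (`_pvalues.py`): the library survival functions are used down to
  p ≈ 1e−280, below which the incomplete-beta power series (F) and the
  upper-incomplete-gamma asymptotic series (chi-square) take over.
  Accuracy is better than 3 significant figures down to p = 1e−300
  (checked against 50-digit arithmetic). Raw p-values are never stored.

### Degenerate inputs

A constant predictor yields a single-category fit flagged `degenerate`;
so does any fit whose categories all merge. Degenerate predictors are
excluded from association testing — symmetrically across all five methods,
so per-method means always average over the same predictor set — rather
than forced into meaningless k = 1 tests.

## Quantile baseline

Quartile binning (n_bins = 4 by default, configurable) with
order-statistic (inverted-CDF) quantiles, so cuts land on observed values
and use the same inclusive-upper-bound assignment as AMC. Under zero
inflation several quantile edges coincide; duplicates collapse, so k ≤ 4.
This collapse — and the consolidation of the whole tail into the top
quartile — is precisely the behaviour AMC is designed to avoid.

## Association battery

* Chi-square: Pearson, no continuity correction (df = k − 1 ≥ 1
  throughout; verified to reproduce all 20 published table results to
  printed precision). Effect size phi = √(χ²/N), equal to Cramér's V for
  k×2 tables.
* Linear trend: univariate logistic regression of the outcome on the
  integer category codes 1…k (equal-spacing assumption; the slope p is
  invariant to the code origin), two-sided Wald test by default with a
  likelihood-ratio option. Under (quasi-)complete separation the Wald
  statistic degenerates, so the score (Rao) test — the Cochran-Armitage
  statistic for ordinal scores — is reported instead and the result is
  flagged. Effect size: Cohen's d with pooled SD, reported as magnitude.
* Untransformed: the same trend test on the raw values.

## Synthetic cohort generator

Each predictor is zero with probability `zero_prob`, otherwise
`positive_shift` + log-normal(`log_mean`, `log_sd`) (a gamma positive part
is available). Case status follows a logistic model on
Σⱼ transform(xⱼ) with slope `effect_size`; the intercept is solved by
root-finding so the population prevalence equals 1/(1 + control_ratio),
and exactly n_cases cases plus control_ratio × n_cases controls are then
drawn without replacement (an informative error asks for a larger
`population_multiplier` if the simulated population falls short).
Reproducibility is exact: every predictor column uses a substream seeded
by (seed, column), outcome and matching draws by (seed, fixed offsets).

Defaults are the emulated study conditions: 4990 cases, 1:4 matched
controls, 50 predictors, zero_prob 0.4, log-normal(−0.5, 1.5), effect 1.0
on the log1p scale. The distributional parameters were chosen so the
simulated marginals resemble the published per-category tables — roughly
40% zeros, most positive mass below 1, tails reaching tens — and the
log1p link encodes the monotone tail-risk pattern those tables display.
What the generator does *not* emulate: correlated predictors
(positive/negative forms of the same concept are near-duplicates in the
real data), demographic confounding and covariate-matched controls, note
count heterogeneity, and any time structure. Passing tests therefore
demonstrate correctness of the algorithms and the direction of the
AMC-vs-quantile contrast under the stated mixture model, not the real
cohort's effect magnitudes; the published headline means are properties
of the source EHR corpus and are reproduced here only directionally.

## Undersampling experiment

Scenarios (500 cases / 2000 controls) and (1000 / 4000), 100 iterations,
top-20 predictors ranked by full-cohort AMC chi-square (selection precedes
subsampling). Both categorizations are re-fit inside every subsample;
a predictor degenerate in a given subsample drops out of that iteration's
denominator. The win fraction is the share of predictors where AMC's
−log₁₀ p exceeds quantile's, averaged across iterations (mean of
fractions); exact ties break by a fair coin so identical arms average to
0.5 (tested). Control draws are simple random — there are no covariates
to match on in the synthetic cohort.

## Problem sizes in checks

The automated checks run at reduced scale chosen to keep the full suite
fast while leaving the statistics well-resolved: greedy-vs-exhaustive
agreement on 100 datasets of n ≤ 200 (where brute force is exact and
cheap); null calibration with 400 predictors at 500 cases / 2000 controls
(99% binomial band ±2.8 points around α = 5%); the method-ranking
comparison over 20 seeds × 20 predictors at 250 cases; the undersampling
check at 30 iterations of 250/1000 from a 1000-case cohort. The analysis
drivers under `analysis/` run the full 4990-case configuration.

## Known limitations

* The greedy path is not globally optimal over all threshold sets; only
  per-step optimality is guaranteed (and tested). This mirrors the
  method's linear-search design.
* Gap restriction can in principle exclude the optimal cut when more than
  1000 distinct gaps exist; in practice cuts worth making sever large
  gaps.
* The F-test selection tends toward the k cap on large n (selection
  p-values keep shrinking); the occupancy floor, not the F test, is then
  the effective regulariser of tail categories.
* Wald trend p-values are anti-conservative under separation-adjacent
  fits; the score fallback bounds the damage but a Firth-penalised fit
  would be principled. Not implemented — univariate tests on n ≥ 2500
  rarely get there.
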