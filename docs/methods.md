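# Methods

This note documents the models, algorithms, defaults and design choices in
`sfimpute`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A quantification matrix is proteins × samples with an explicit missingness
mask (`NaN`), never sentinel zeros: a zero in an LFQ export is ambiguous
between true absence, sub-detection-limit presence and software artifacts,
so the set of cell tokens read as "missing" (empty, `NA`, optionally `0`)
is configurable at parse time. Matrices carry a `raw`/`log2` scale flag.
Filtering on abundance operates on the raw scale (the conventional
2¹⁵ = 32 768 low-intensity floor applies to raw intensities); every
imputation and test operates on log2 intensities, where protein abundances
are approximately Gaussian and fold changes are differences.

## Selection and filtering

Contaminants (cRAP / MaxQuant-style accession lists, with optional
`CON__`-prefix stripping) are removed first. Two sparsity rules follow,
both on by default and combined as a union because they guard different
failure modes:

* *sparse*: ≥ 50% of a protein's samples are missing **or** below the
  intensity threshold — a missing cell cannot certify abundance above the
  limit, so it counts as below;
* *min_obs*: fewer than 3 observed values — too few for any within-group
  variance estimate.

At exactly 50% the sparse rule fires (the comparison is
`fraction ≥ sparse_fraction`); this boundary choice is deliberate and
configurable.

## Imputation strategies

All imputers return a complete matrix and never modify an observed cell
(the test suite checks this bitwise). Deterministic methods (kNN, SVD,
MinDet, conditional-mean MLE) are reproducible without a seed; stochastic
ones take an explicit seed.

**kNN** (MAR). For a missing cell (g, j), donor rows are those observing
column j; distance to a donor is Euclidean over mutually observed columns,
scaled by √(n_columns / n_overlap) so that small overlaps are not rewarded
for having fewer terms. The k nearest donors contribute an
inverse-distance-weighted mean; exact-duplicate donors (distance 0) get
weight 1/ε with ε = 10⁻¹⁰. With no eligible donor the row's observed mean
is used, with a warning.

**SVD** (MAR). Missing cells start at their row mean; each sweep takes the
rank-k SVD of the filled matrix and regresses every incomplete row's
observed entries on the top right-singular vectors ("eigenproteins" span
the row space; the regression uses the eigen-sample basis), replacing the
row's missing entries with fitted values. Convergence metric: root
sum-of-squares change of the imputed cells, divided by the Frobenius norm
of the matrix (an absolute variant is available); default threshold 0.01,
maximum 100 sweeps with a warning on non-convergence.

**MLE** (MAR). Protein rows are modelled i.i.d. multivariate normal over
samples; θ = (μ, Σ) is fitted by EM to a log-likelihood tolerance of 10⁻⁴,
grouping rows by missingness pattern so the per-sweep cost scales with the
number of patterns. Near-singular Σ receives a small trace-proportional
ridge with a warning. Each row's missing block is then drawn from the
conditional normal given its observed entries ("draw" mode, the default,
because a single conditional mean understates uncertainty inside the MI
loop); a deterministic conditional-mean mode exists for testing.

**MinDet** (MNAR). Every missing cell in sample j becomes the
`mindet_quantile` (default 0.01) quantile of that sample's observed
values; a global pooled-quantile mode is available (both readings of
"smallest detectable intensity" are supported; per-sample is the default
because detection limits drift between runs). Bitwise-deterministic, so
all across-iteration spreads downstream are exactly zero.

**MinProb** (MNAR). Gaussian draws centred on the MinDet value with SD
equal to `minprob_sigma_scale` × the median of per-row observed SDs — a
global, robust spread chosen over per-sample SDs because three-sample
columns estimate spread poorly. As the scale → 0 the method degenerates to
MinDet.

**QRILC** (MNAR). Per sample, the missing fraction π is read as censored
mass in the left tail. The observed values are the upper (1 − π) tail of
the underlying normal, so the empirical quantile of the observed values at
tail probability (p − π)/(1 − π) estimates the full distribution's
p-quantile. Ordinary least squares of those quantiles on Φ⁻¹(p) over 100
evenly spaced p in (π + 0.001, 0.999) yields intercept μ̂ and slope σ̂;
missing cells are drawn from Normal(μ̂, `qrilc_sigma_scale`·σ̂) truncated
above at μ̂ + σ̂ Φ⁻¹(π). Columns need ≥ 4 observed values; the slope is
floored at 10⁻⁹ against degenerate fits.

**Hybrid (SFI-hybrid, kNN + QRILC).** The model selector computes each
row's mean observed log2 intensity and sets the censoring threshold at the
quantile of these means with probability equal to the matrix's overall
missing fraction; rows below the threshold are flagged MNAR (0), the rest
MAR (1). With no missingness the threshold is the 0-quantile and everything
is MAR. Forced all-MAR / all-MNAR modes exist (the pure-MAR strategies use
all-MAR to disallow left-censored values). The hybrid applies the selector
*within each treatment group's column block* and imputes MAR rows with kNN
and MNAR rows with QRILC inside that block only: a protein absent from one
condition is treated as left-censored there while its observed condition is
untouched. A row with no observed value inside a block has no defined mean
and is flagged MNAR — exactly the presence/absence case QRILC models. The
kNN/QRILC pairing is the default but the sub-methods are pluggable, and any
single method can optionally be run per group.

The quantile rule for the selector threshold is a documented
reconstruction: the workflow this package follows inherits the selector
from its software lineage without printing the rule, and the chosen form
reproduces the intended left-censoring semantics while staying exposed as
configuration.

## Differential expression

Per protein, with groups of n₁ and n₂ samples and d = n₁ + n₂ − 2 residual
degrees of freedom, the pooled variance s²_g is shrunk toward a prior:
s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d), and
t_g = logFC_g / (s̃_g √(1/n₁ + 1/n₂)) is referred to a t distribution on
d₀ + d degrees of freedom (capped at the total pooled df across proteins).
The prior (d₀, s₀²) is fitted by matching the mean and variance of
log s²_g to a scaled inverse-χ² model using digamma/trigamma moments; the
trigamma inversion uses Newton iteration, d₀ is capped at 10⁶ as the
infinite-shrinkage flag, and when the observed spread of log-variances is
no larger than sampling noise the prior variance falls back to the mean
observed variance. Zero variances are excluded from the fit (all-zero
variances are an error — no prior is estimable). One test cross-checks the
statistic against the reference empirical-Bayes implementation in R to
rtol 10⁻⁸; the two limiting cases (d₀ = 0 → classical pooled t; d₀ → ∞ →
constant variance) are asserted exactly.

P-values are two-sided. Benjamini–Hochberg step-up adjustment is
implemented directly (and cross-checked against `statsmodels`); Storey
q-values scale the BH quantity by π̂₀ estimated on the λ-grid
0.05, 0.10, …, 0.95 with a cubic-polynomial smoother evaluated at λ = 0.95,
clipped to (1/n, 1]. With fewer than 10 p-values π̂₀ is fixed at 1. A
protein is significant when q < α (strict, default α = 0.05).

## Multiple imputation

Iteration i of m (default 25) uses seed `base_seed + i`; for kNN and SVD
the neighbour count / component count equals i (capped at the matrix
limits), so early iterations are aggressive and later ones smooth — the
across-iteration spread then brackets the method's sensitivity to its own
main tuning knob as well as to the random draws. Each iteration imputes,
quantile-normalizes (sorted columns replaced by the vector of row-wise
means of the column-sorted matrix; ties share the average of their
quantile means) and tests. Combination uses across-iteration means and
SDs of logFC and −log10 q and the mean q-value, with proteins ranked by
mean q (ties by accession) and called significant at qmean < α. This
mean-combination is a deliberate fidelity choice for the workflow being
implemented; Rubin's pooling rules are out of scope. Rows whose m values
are bitwise identical get an exact zero SD (guarding against
mean-accumulation rounding), so deterministic imputers report exactly zero
spread at any m. q-values are floored at 10⁻³⁰⁰ before the −log10.

## Synthetic data and amputation

`generate_ground_truth` emulates a two-group (default 3 vs 3) whole-cell
LFQ experiment on the log2 scale: baseline abundances Normal(20, 2) (log2
intensities of mid-abundance proteins on an Orbitrap-class instrument),
replicate noise Normal(0, 0.5) (typical LFQ within-group SD), and a
default 50% of proteins carrying effects drawn Normal(0, 2) added to the
treatment group — a strong contrast, matching the kind of
treatment-vs-deprivation designs the workflow targets. Amputation defaults
to a 0.5 : 0.5 MAR : MNAR mix; the benchmark grid also uses 0.2:0.2,
0.8:0.2 and 0.2:0.8.

`ampute` masks only rows that are complete. Each mechanism builds its own
candidate mask: a per-row deletion pattern (default: one single-column
pattern per sample, matching the dominance of single missing cells in
mixed designs; multi-column patterns are configurable) and a weighted-sum
score — for MAR the weighted sum of the values that would remain observed,
for MNAR the value that would be deleted, with MNAR pattern choice itself
weighted toward low cells so deletion prefers the left tail even at
proportion 1. Scores are standardized and passed through a unit-steepness
logistic link (`left`/`right`/`mid`/`tail` orientations, plus an explicit
`mcar` constant link); the link's shift is solved numerically (Brent) so
the expected masked fraction equals the requested proportion exactly. A
uniform allocation vector over the mechanisms with positive proportion
picks, per row, which mechanism's outcome applies, and per-cell labels
(`MAR`/`MNAR`/`MCAR`) are returned for evaluation.

`simulate_from_template` resamples a real matrix per protein per group
from Normal(observed mean, observed SD), replicating single observations
with zero SD (warned) and preserving fully-missing groups, so
presence/absence structure survives simulation.

What the generator does *not* emulate: peptide-level structure and
roll-up, correlated protein co-expression (rows are independent given the
group means), batch effects, heavy-tailed or multiplicative noise, and
intensity-dependent variance trends. Passing tests on these fixtures
therefore demonstrate mechanism-level correctness and calibration of the
pipeline, not performance on any particular real dataset.

## Problem sizes and numerical choices

The test suite and acceptance script run at fixture scale chosen to keep
estimates stable while staying quick: 1000-protein matrices for
calibration and capture-rate runs, 2000 rows for mechanism-contrast rank
tests, 50 replicates for QRILC parameter recovery, 25 MI iterations in the
acceptance runs and 2–5 in unit tests of the loop mechanics. Other
numerical details: kNN ε = 10⁻¹⁰; SVD tolerance 0.01 (tightened locally in
exact-recovery tests); EM tolerance 10⁻⁴ with trace-scaled ridge on
near-singular covariance; QRILC slope floor 10⁻⁹; q floored at 10⁻³⁰⁰
inside −log10; tie-breaks by accession everywhere a deterministic order is
needed; rating ties share the mean rating so per-method totals remain
comparable.

## Known limitations

* Two-group contrasts only; no factorial designs or variance-trend priors.
* The moderated-t prior has no intensity trend.
* MI combination is mean-based, not Rubin's rules, by design fidelity.
* kNN cost is O(rows²) per iteration in the worst case; fine at
  proteome scale (10³–10⁴ rows) but not optimized beyond vectorized
  distances.
* The model-selector threshold rule is a reconstruction (see above) and is
  exposed as configuration rather than asserted as the unique reading.
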