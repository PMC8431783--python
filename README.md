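# sfimpute

Left-censored missing-value imputation and multiple-imputation differential
expression for bottom-up, label-free quantitative (LFQ) proteomics.

## The problem

Data-dependent acquisition proteomics routinely leaves 5–50% of protein
intensities unobserved in any given replicate. Those gaps are a mixture of
mechanisms: value-independent losses (MCAR/MAR — mis-mapped peptides,
stochastic precursor sampling) scattered across the intensity range, and
intensity-dependent, *left-censored* losses (MNAR — peptides below the
effective detection limit). A single imputation strategy tuned to one
mechanism distorts fold changes and false-discovery control when the other
mechanism is present, and a single imputed value hides how sensitive the
downstream statistics are to the guess.

`sfimpute` implements a Selection–Filter–Imputation (SFI) workflow that
addresses both issues:

* **Seven imputation strategies.** MAR family: k-nearest-neighbour rows
  (kNN), iterative low-rank SVD completion, and EM maximum-likelihood under
  a row-i.i.d. multivariate normal (MLE). Left-censored MNAR family:
  deterministic low-quantile replacement (MinDet), Gaussian draws centred
  on that quantile (MinProb), and quantile-regression imputation of
  left-censored data (QRILC), which recovers the uncensored Normal(μ, σ)
  per sample from a normal Q–Q regression of the observed order statistics
  and draws from its truncated left tail.
* **A hybrid model selector.** Each protein is flagged MAR or MNAR by
  comparing its mean observed log2 intensity with the quantile of all row
  means at probability equal to the overall missing fraction; MAR rows are
  imputed by kNN and MNAR rows by QRILC, *separately within each treatment
  group*, so presence/absence proteins are treated as censored only where
  they are actually absent.
* **Multiple imputation (m = 25).** Each iteration re-imputes with a fresh
  seed (and, for kNN/SVD, k or the component count equal to the iteration
  index), quantile-normalizes, and tests each protein with an
  empirical-Bayes moderated t-statistic
  t_g = (x̄₁ − x̄₂) / (s̃_g √(1/n₁ + 1/n₂)), where
  s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d) shrinks the pooled variance toward a
  moment-matched scaled inverse-χ² prior. P-values are Benjamini–Hochberg
  adjusted and converted to Storey q-values; proteins are ranked by their
  across-iteration mean q-value, and the spread of logFC and −log10 q over
  iterations quantifies imputation uncertainty.

A simulation/amputation layer generates complete two-group datasets with
known effects and introduces MAR/MNAR/MCAR missingness at controlled
proportions, and an evaluation layer scores methods by capture rate against
ground truth, missingness bins, merged top-protein lists and rank-ratings.

## Worked example

```python
import sfimpute as sf

# a 500-protein two-group (3 vs 3) ground-truth dataset with mixed
# 0.5 : 0.5 MAR : MNAR amputation
gt = sf.generate_ground_truth(n_proteins=500, seed=7)
print(round(gt.amputed.missing_fraction, 4))      # 0.076

model = sf.MIDifferentialExpression(
    gt.amputed, gt.groups,
    sf.MIConfig(m=25, params=sf.ImputeParams(method="hybrid"), base_seed=7),
)
res = model.fit()
print(res.summary())
```

```
Multiple-imputation differential expression
==============================================
method: hybrid    iterations: 25    base seed: 7
contrast: treatment vs control
proteins: 500    significant (qmean < 0.05): 198

top proteins by mean q-value:
        logfc_mean  logfc_sd     qmean  rank
P00176      -5.139         0 1.706e-12     1
P00127       4.757         0 1.947e-12     2
P00114       4.882         0 2.478e-12     3
P00115       4.636         0 7.888e-12     4
P00230      -4.433  0.006098 1.457e-11     5
```

198 of the 500 proteins clear the q-value-mean < 0.05 cut. Each top protein
shows its across-iteration mean log2 fold change (treatment − control), the
standard deviation of that fold change over the 25 imputations (0 where
every missing cell of the protein fell outside the contrast or the draws
agreed), and the mean q-value that drives the ranking.

The same pipeline is available from the shell:

```bash
sfimpute simulate  --config sim.yaml       # write a ground-truth bundle
sfimpute run       --config run.yaml       # filter + MI-DE on a real matrix
sfimpute benchmark --config bench.yaml     # score methods against a bundle
```

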