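# Methods

## Model

The focal quantity is a gene's *regulatory variant-set*: the aggregate
cis-genetic component of its expression, summarised by an elastic-net
linear model over the SNPs from 1 Mb upstream of the transcription start
site to 1 Mb downstream of the termination site (inclusive, 1-based;
strand is ignored for window construction). The model's prediction
`pred^A` stands in for the variant-set in every downstream test.

Two complementary signatures of an interaction between the variant-set and
an unobserved or distal factor are used:

* **veQTL screen.** `obs^A` is regressed on `pred^A`; Spearman's rank
  correlation between `pred^A` and the squared residuals detects
  variance that tracks the variant-set. The p-value uses the t
  approximation with average ranks (two-sided; the direction of a genuine
  variance increase is positive rho, but the screen is reported
  two-sided as the sign is not known a priori).
* **Interaction scan.** For each distal gene B,
  `obs^A ~ pred^A + obs^B + pred^A·obs^B` is fitted by OLS and the product
  term tested with an ANOVA F-test against the nested no-interaction
  model. Discoveries require replication: BH-FDR < 0.05 in cohort 1
  (across all tested pairs), BH-FDR < 0.05 in cohort 2 recomputed over
  only the cohort-1-significant pairs (the actual replication burden), and
  a concordant coefficient sign (exact zeros count as discordant).

Sign concordance of significant pairs versus all tested pairs is compared
with a Pearson chi-squared test over the four sign combinations
(`-/-`, `-/+`, `+/-`, `+/+`; df = 3).

### Confounder exclusion

A replicated pair is discarded when a simpler explanation fits: any single
SNP in gene A's cis window, or the expression of any third gene C, added to
the model **together with its own `pred^A` interaction**, removes the
significance of the `pred^A·obs^B` term (BH-adjusted across the pair's
candidate refits; "lost" means adjusted FDR >= 0.05 for at least one
candidate). Including the candidate's interaction term is essential: a
candidate that truly carries the interaction leaves the proxied
`pred^A·obs^B` term nothing to explain, whereas a main-effect-only
adjustment cannot absorb an interaction at all. The same structure is used
when adjusting for all of gene B's model SNPs jointly (main + `pred^A`
interaction per SNP), and a predicted-by-predicted fit
(`obs^A ~ pred^A + pred^B + pred^A·pred^B`) asks whether the channel is
genetic–genetic. The final putative set is, by construction, the
replicated set minus the SNP-explained and third-gene-explained pairs;
the pipeline asserts this identity on every run.

### Variance decomposition

Nested Gaussian fits (cis-only; + distal main effect; + interaction) are
compared via pseudo-R² = (null deviance − residual deviance)/null deviance,
which equals the classical R² for least squares; increments are reported
per term. For genes with ≥ 2 putative partners, partners are pruned at an
absolute-correlation cutoff of 0.4 (greedy: while any |r| exceeds the
cutoff, drop the violating member with the largest mean absolute
correlation; ties fall to input order), then stepwise regression is
repeated 100 times on random 80/20 train/test splits with randomised
partner order. The search is bidirectional on AIC (k = 2) between the
cis-only lower scope and the full main + interaction upper scope,
respecting marginality (an interaction enters only after its main effect,
a main effect leaves only after its interaction). Test-fold pseudo-R² uses
held-out predictions against the held-out null deviance; the
interaction-only share is the full-model test pseudo-R² minus the
same-predictors main-effects-only refit on the same split. Training
increments are reported alongside test-fold values.

### Enrichment

Interacting partner genes are tested against the tested background with an
upper-tail hypergeometric test, BH-adjusted across sets. For per-gene
numeric scores, the foreground median is compared with the 2.5th–97.5th
percentile band of medians from 100 same-size random background draws.

## Preprocessing

Expression is cleaned once, and the residuals stand in for observed
expression everywhere:

1. **Fixed effects** (sex, age in years, five ancestry PCs) by least
   squares per probe; a rank-deficient design fails loudly naming the
   offending covariate.
2. **Batch factors** (plate, array) as random intercepts estimated by
   method-of-moments shrinkage, `μ_k · σ_b²/(σ_b² + σ_e²/n_k)`, gated by a
   per-probe one-way ANOVA F test at the 0.95 quantile so pure-noise batch
   structure is not chased. The fixed/batch removal is iterated to its
   fixed point, making the whole operation idempotent to machine
   precision.
3. **Hidden factors** by PCA on probe-standardised residuals
   (correlation scale, so no single high-variance probe can masquerade as
   a global factor), with the number of factors chosen by a
   parallel-analysis permutation criterion: factors are kept while the
   observed eigenvalue exceeds the 95th percentile of same-rank
   eigenvalues from 99 column-permuted matrices. The criterion has a ~5%
   per-dataset false-positive rate by construction. Retained factors are
   projected out of the unscaled residuals, which can only reduce probe
   variance.
4. **Kurtosis filter**: genes whose biased moment-ratio kurtosis
   `(Σd⁴/n)/((Σd²/n)²)` (Gaussian ≈ 3) exceeds 9 are excluded, applied to
   observed *and* predicted expression; the kurtosis gate is applied
   before the transfer-R² gate. Zero-variance genes are excluded as
   degenerate. The biased estimator is used deliberately — it is the
   plain moment-ratio convention of R's `moments` package.

## Cis models

Dosages are mean-imputed per SNP and standardised; weights live on the
standardised scale with the training means/SDs stored for transfer.
The elastic-net mixing parameter is fixed at 0.5 (the PredictDB
convention); the penalty strength is chosen by 10-fold CV, and the
reported CV R² is the squared Pearson correlation of out-of-fold
predictions with the phenotype using a fold split *independent* of the one
that chose the penalty, so the estimate carries no selection optimism.
Its p-value comes from the correlation test (anti-predictive models get
p = 1), BH-adjusted across genes with an FDR < 0.05 gate. Genes are
retained when additionally their predictions pass the kurtosis filter in
every cohort and the prediction R² is ≥ 0.1 in both the training CV and
the external transfer; a gene with > 20% of its nonzero-weight SNPs
missing in the target cohort is non-transferable. The lead-eQTL
alternative takes the SNP with the largest absolute marginal correlation
and a phenotype-permutation p-value `(1 + #better)/(1 + n_perm)` (defaults:
1000 permutations, seed 123456789), plus the R² of regressing expression
on that SNP's dosage.

## Synthetic cohorts

The generator emulates a two-cohort design (defaults 876 and 344
individuals) sharing cis architecture: per gene, 50 window SNPs with MAF ~
U(0.05, 0.5) under Hardy–Weinberg with no LD, 5 causal SNPs with positive
weights, and a genetic score centred and scaled to unit variance using the
Hardy–Weinberg moments of the shared frequencies (so the standardisation —
and hence the planted heritability, default h² = 0.3 — is identical across
cohorts). Expression is

`obs = √h²·s + β_b·b_B + β_ab·√h²·s·b_B + covariates + batch + noise`

with `b_B` the partner's pre-nuisance expression, fixed age/sex/PC effects,
plate and array random intercepts (SD 0.3 and 0.15), and per-cohort noise:
cohort 1 Gaussian with sd 0.84 (≈ √(1−h²), so a plain gene has unit
variance), cohort 2 sd 1.0 with an optional mean–variance coupling to
mimic count-derived data (off by default, so null cohorts are
homoskedastic). A configurable fraction of non-interacting genes receives
Student-t (df = 3) noise to exercise the kurtosis filter. Ancestry PCs are
independent Gaussians — nuisance covariates only, with no population
structure model. Interaction targets may not themselves serve as partners
(the generative graph must be acyclic), and planting an interaction on a
gene without cis signal is rejected as unidentifiable.

Because the score is centred, a pure interaction (`β_b = 0`) leaves the
marginal correlation between the two genes near zero — interacting pairs
are barely co-expressed (mean |r| ≈ 0.03 at the default sizes) — while the
conditional variance `σ_e² + (β_b + β_ab·√h²·s)²·Var(b_B)` still grows
along the observed score range through the score's right skew (positive
weights on minor alleles). The variance-demo conditions
(`veqtl_demo_config`: β_ab = 1.2, β_b = 0.6, two causal variants with MAF
0.05–0.25) place the vertex of that parabola below the observed score
range, the regime in which expression is high only under the right
combination of variant-set and partner level and the variance screen has
essentially full power at n = 876.

What the generator does *not* emulate: linkage disequilibrium, genotype
missingness/imputation quality, population structure in the PCs,
probe-level microarray artefacts, or count noise (beyond the optional
mean–variance coupling). Passing tests therefore demonstrate the
statistical machinery under the stated generative model, not robustness to
those real-data features.

## Numerical choices and problem sizes

* All OLS fits use `numpy.linalg.lstsq`; nested F-tests take their degrees
  of freedom from matrix ranks, so collinear covariates cannot inflate a
  test. Pairs with |r(pred^A, obs^B)| > 0.999 are flagged untestable
  rather than fitted.
* BH-FDR is `statsmodels` `multipletests(method="fdr_bh")`; Spearman,
  Pearson, F, χ² and hypergeometric distributions come from `scipy`.
* The elastic-net engine is scikit-learn's coordinate descent; the test
  suite checks it against an independently written coordinate-descent
  oracle on small problems (≤ 1e-6).
* All pipeline randomness derives from one master seed through named
  substreams (`stage_seed`), so each stage is individually reproducible
  and a fixed-seed run writes byte-identical outputs (fixed float
  formatting, sorted JSON keys).
* Monte-Carlo problem sizes were chosen so each check estimates its
  quantity with standard error well inside the asserted tolerance: 2000+
  replicates for type-I error, 500 for p-value uniformity (KS), 100
  replicate genes for veQTL power, 20 seeds for planted-scan recovery and
  confounder flagging (flag decisions take the union over the two
  simulated cohorts, as the pipeline removes pairs flagged in either
  dataset), and 200 null genes × 1000 permutations for the lead-eQTL
  calibration.
* The third-gene scan in the pipeline restricts candidates to the other
  members of gene A's interaction network plus a seeded random draw of
  background probes (configurable; the exhaustive scan is O(pairs ×
  probes)).

## Known limitations

* The veQTL screen's power depends on the asymmetry of the conditional
  variance over the observed score range; a symmetric pure interaction on
  a symmetric score is nearly invisible to a rank-correlation screen even
  when the interaction F-test finds it easily.
* Method-of-moments random intercepts are a shrinkage approximation to the
  mixed-model BLUP; with very small batches the F-gate can leave residual
  batch structure.
* Stepwise selection with AIC admits null terms at the well-known ~16%
  rate implied by the penalty of 2; selection frequencies, not single-run
  term lists, are the interpretable output.
* The untestable/degenerate paths (monomorphic windows, constant
  predictions, overfit eQTL adjustments) return flagged results or raise
  named errors rather than guessing.
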