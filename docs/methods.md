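# Methods

This note documents the models behind `helpmeth`, the choices made
where the assay or the analysis convention left the design open, and
what the synthetic-cohort validation does and does not establish.

## Angle-metric quantification

HELP-tagging reads out methylation by comparing HpaII (methylation-
sensitive) and MspI (insensitive) tag counts at CCGG sites.  Both
libraries are scaled to counts per million (CPM) of their totals; the
score is `100 * (1 - arctan(h/m) / (pi/2))`, where `h` is the sample's
HpaII CPM and `m` the pooled-reference MspI CPM.  The formula fixes the
metric's documented endpoints — 100 when HpaII is fully blocked
(methylated), 50 at `h = m`, approaching 0 as HpaII dominates — and is
monotone in each argument.  Scores are reported on 0–100 so the
10-unit effect gate of the differential calls applies literally.

Sites whose raw MspI reference count is below 4 are flagged as
unquantifiable (returned as NaN) rather than scored; zero HpaII counts
map exactly to 100 with no pseudo-count smoothing.

CPM normalisation makes the score compositional: a genome-wide shift
of methylation is partially absorbed by the library totals, so only
the relative (between-sample, between-site) structure is identified.
This is visible in the batch-correction experiment below, where a
planted 10-unit offset appears as ~6 units after quantification.

## Synthetic cohort generator

The generator emulates the study design end to end:

* **Cohort** — 15 control, 11 hypertension-only, 36 PE samples.
  Maximum systolic/diastolic blood pressure is drawn per group around
  the published medians (control ~130/81, hypertension ~160/100, PE
  ~175/106 mmHg); proteinuria is grade 0 outside PE and grades 1/2/3
  with probabilities 13/30, 8/30, 9/30 within PE.  Binary covariates
  (sex, primiparity, MgSO4 treatment, ...) follow the published group
  rates.  Batches are assigned round-robin within group, so batch is
  balanced against outcome by construction.
* **Methylome** — each site draws a baseline level from a three-part
  mixture: U(12,30) (CpG-island-like, weight 0.171), U(30,70)
  (intermediate, 0.2), U(70,90) (methylated, 0.629).  The weights are
  fixed so that the methylome-wide mean of `tan((1-m/100)*pi/2)` is 1
  under the default within-group noise; this makes the
  library-composition factor of CPM normalisation ~1 and the angle
  score calibrated (unbiased at depth).  The component bounds keep
  ≥2.5 sd of headroom to the 0/100 boundaries so the Gaussian
  within-group noise is effectively uncensored by clipping.
* **Cell mixture** — the amnion is epithelium-dominant, so the sample
  AE fraction is Beta(8,2) (mean 0.8).  `n_celltype_dmr` loci
  (default 150) are AE/AS-discordant at 85 vs 15 score units, half in
  each direction; all other loci are concordant.  One discordant locus
  (configurable) additionally carries a proteinuria effect, providing
  the phenotype-confounded reporter-candidate scenario.
* **Planted effects** — three disjoint classes of 40 loci each start
  from intermediate baselines and receive score shifts linear in
  (SBP − 130 mmHg) at 0.4 units/mmHg, in proteinuria grade at 6
  units/grade, or both.  40 further loci have their within-group noise
  variance inflated 25-fold in PE samples only.
* **Noise and batches** — every entry gets Gaussian biological noise
  (sd 4 score units, a realistic inter-individual spread well below
  the 10-unit call gate); each batch applies a location offset and a
  residual scale factor (`x = signal + loc_b + scale_b * eps`), which
  is exactly the model the empirical-Bayes batch adjustment assumes.
  Scores are clipped to [0, 100].
* **Counts** — MspI reference counts are Poisson around a log-normal
  site weight times the mean depth (one pooled library).  HpaII counts
  are negative binomial (dispersion 0.05 by default, Poisson in the
  zero-dispersion limit) around
  `weight * depth * library_factor * tan((1-m/100)*pi/2)` — the tan
  link is the exact inverse of the angle transform, so deep-coverage
  quantification recovers the planted truth without bias; the
  tan argument is capped at 0.995·(pi/2) to keep expectations finite
  at fully unmethylated sites.
* **Bisulfite isolates** — per CpG and replicate (default 5 per cell
  type, Poisson depth 10), methylated reads are binomial with the cell
  type's true level.

What the generator does **not** emulate: read-level data, genotype or
meQTL structure, spatially correlated methylation along the genome,
assay GC/fragment-length biases, or cell-composition shifts that
correlate with the phenotype.  Passing tests therefore demonstrate
internal consistency of the statistical chain under its stated model,
not robustness to those real-data complications.

## Batch adjustment

Parametric empirical-Bayes location/scale adjustment: each feature is
standardised under a model containing batch indicators plus the
protected outcome design (dummy-coded groups); per-batch feature means
(gamma) shrink toward a normal prior and residual variances (delta^2)
toward an inverse-gamma prior, hyperparameters by method of moments,
iterated to relative tolerance 1e-4.  The parametric variant was
chosen because it is deterministic and the generator's batch model is
exactly its assumed form.  Singleton batches skip the scale step with
a warning; adjusted scores are clipped back to [0, 100] and the
clipped fraction recorded.  The implementation is validated against
the reference R implementation (`sva::ComBat`) to 1e-3.

## Composition reporter and pruning

AE-vs-AS differentially methylated CpGs are called by pooling
replicate counts per cell type (low-coverage data cannot support
per-replicate tests) and applying the two-sided Fisher exact test at
p < 1e-5.  HpaII sites coinciding with DMR CpGs become reporter
candidates.  Candidate selection mirrors the published logic: a
candidate is excluded if its methylation associates with either
phenotype axis (min p of regressions on max SBP and proteinuria grade
below 0.01); among the rest the one most associated with the matrix's
first principal component — the dominant variability axis that
composition drives — is the reporter.  The PC1 regression is this
package's concrete proxy for "association with methylation
variability"; any monotone variability statistic would serve.

Pruning removes the reporter and every site with |Spearman rho| > 0.3
against it.  The absolute value is deliberate: composition shifts push
AE-hypermethylated and AS-hypermethylated loci in opposite directions,
so signed pruning would keep half the composition signal.  Constant
sites (undefined rho) are retained with a warning.  A weak coherent
composition echo survives pruning — per-sample CPM normalisation
factors track the AE fraction — but the axis is strongly attenuated
(verified in tests).

## Differential methylation

"ANOVA significance" is implemented as the F-test of each fitted model
against the intercept-only null; model 3 uses the joint 2-df test.
Benjamini–Hochberg adjustment is applied per model across all retained
sites.  The effect gate is the absolute difference of PE and control
group means (hypertension samples excluded), on the post-adjustment
scale.  Constant sites receive p = 1 by convention.  Because maximum
SBP and proteinuria grade are strongly correlated in the cohort (both
track PE severity), the single-covariate models call overlapping site
sets; disjoint calls arise only under orthogonal covariate designs.

## Variance screen

The variance ratio is PE over control (unbiased sample variances),
with the two-sided p `2*min(P(F<=r), P(F>=r))` at (n_PE−1, n_ctrl−1)
degrees of freedom, BH-adjusted; calls additionally require a
PE-inflated direction, matching the motivation that PE heterogeneity
(early- vs late-onset, severity spectrum) widens the exposed group.

The stringent gate (adjusted p < 1e-7 with ratio > 20) has
intrinsically low power at these group sizes: with 14 denominator
degrees of freedom, an adjusted p below 1e-7 requires an *observed*
ratio of roughly 50–65 even before multiplicity sharpens the
threshold, so true 25-fold inflations are called only when the sample
ratio fluctuates far upward (a few percent of loci).  The acceptance
report states the honestly measured sensitivity; loci that survive
this gate in real data necessarily carry observed ratios far above 20.
Zero-variance sites are skipped with a warning.  Gene assignment uses
half-open gene intervals extended ±50 kb; a site counts once per
overlapping gene.

## Cohort statistics

Categorical characteristics are tested with the Fisher–Freeman–Halton
exact r×c test across all three groups: the p-value sums the
multivariate hypergeometric probabilities of every margin-preserving
table no more probable than the observed one, with a 1e-7 relative
tolerance for probability ties (the convention of standard statistical
software).  Full enumeration is used within a configurable budget; a
seeded Monte-Carlo mode (Patefield sampling) covers larger tables.
Continuous variables use the pooled-variance t-test (two groups) or
one-way ANOVA (three), computable identically from raw values or from
(mean, sd, n) summaries — the summary path exists because published
characteristics tables print only summaries.

## Numerical and validation choices

* Coordinates are 0-based; BED intervals half-open; the ±28 bp SNP
  window is closed at both ends (a SNP exactly 28 bp away excludes the
  site), with the boundary exposed as a parameter.
* Sex chromosomes are recognised by name ({chrX, chrY, X, Y}).
* One global seed drives per-stage independent substreams, so each
  generator stage is reproducible in isolation and stage reordering
  cannot silently change results.
* Calibration and recovery experiments (tests and the acceptance
  script) run at 10,000 sites with deep coverage and near-zero count
  dispersion: the call gates concern the biological score-scale
  signal, and this regime isolates it from assay noise, which is
  exercised separately (quantification round-trip, batch experiments,
  full-pipeline runs at default depth).  These sizes complete in
  seconds on one CPU.
* The default full-pipeline cohort is 5,000 sites × 62 samples.

## Known limitations

* The variance screen's power analysis above means its planted-effect
  sensitivity is small at the default 25-fold inflation; detecting
  moderate inflations reliably would require either larger control
  groups or a relaxed gate.
* The exact r×c test is exponential in table size; beyond the
  enumeration budget only the Monte-Carlo estimate is available.
* Compositional (CPM) quantification cannot recover genome-wide mean
  shifts; all downstream statements are about relative methylation.
* PCA covariate attribution reports association, not causal
  decomposition; correlated covariates share components.
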