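# Methods

## The R/G ratio

For a features × samples table of raw counts with each feature tagged *gene*
or *repeat* (repeat rows named `subfamily:family:class`), sample *s* is
summarized as

R/G(s) = median_f∈repeats x_fs / median_f∈genes x_fs,

where x_fs = log2(c_fs / σ_s + ψ) is the normalized log-scale expression,
σ_s the sample's size factor and ψ a pseudocount (default 1). Medians over an
even number of values are the mean of the central pair, everywhere in the
package. Both medians are taken over **all** annotated features of the
relevant kind, zero-count rows included — this reads "all repeat transcripts /
all gene transcripts" literally; `nonzero_only=True` restricts to features
detected somewhere in the cohort, and the choice is recorded in the run
manifest. A zero gene median (possible only with a pseudocount below 1 or a
degenerate table) is an error rather than an infinite ratio.

Size factors are median-of-ratios: factor_s = median over features with
all-positive counts of c_fs / geomean_f. A single-sample table gets factor 1
by convention; a table with no universally detected feature is rejected
(a pseudo-reference fallback is deliberately not implemented). The log2
transform is a surrogate for regularized-log / variance-stabilizing
transforms: the downstream statistic is a ratio of medians, which is
insensitive to the fine shape of any monotone, roughly logarithmic transform,
so exact reproduction of shrinkage-based transforms is out of scope. The
transform name and pseudocount travel with the matrix as provenance.

## Stratification

Cohort ratios are z-scored (sample sd, divisor n−1) and the z-score **range**
is cut into three equal-width, right-closed intervals; the lowest interval
also contains the minimum. A value equal to an interior edge belongs to the
lower bin. Labels are `low`/`mid`/`high` in ascending order. Equal-range bins
are invariant under positive affine transforms, so z-scoring cannot change the
labels — it is kept because the z-scores themselves are reported. Degenerate
cohorts (all ratios equal) carry no range information; every sample is
labelled `mid` rather than inventing extremes. Stratification is performed
within one cohort at a time; strata are generally *not* equal-sized.

Repeat-class composition profiles are fractions of **raw** reads (per-class
repeat reads over all repeat reads, and repeat reads over all reads), since
they describe where reads align, not model-scale expression. DNA transposons
and any unclassified repeat classes are reported as their own classes.

## Differential expression

Between-stratum contrasts (high-vs-mid, low-vs-mid) use a two-group
negative-binomial Wald test on size-factor-normalized counts, variance
μ + αμ². Per feature, the dispersion α is a pooled method-of-moments
estimate — within-group sums of squares with combined degrees of freedom, so
it remains valid when the group means differ — floored at 1e-8. The fold
change is log2((m_B+ε)/(m_A+ε)) with ε defaulting to half the smallest
positive normalized count in the table (configurable), which prevents
infinite fold changes at zero means; ε is recorded on the result. The Wald
statistic (fold change over its delta-method standard error) is referred to a
t distribution with n_A+n_B−2 degrees of freedom rather than the normal: at
the cohort sizes this package targets (≈10 per group) the plug-in variance
estimate is noisy enough that the normal reference is measurably
anti-conservative (empirical type-I error ≈ 0.07 at nominal 0.05 in the null
simulations below), while the t reference is calibrated and converges to the
normal as groups grow. No fold-change shrinkage or covariate adjustment is
attempted — the test is a calibrated two-group contrast, validated by
simulation, not a reimplementation of any particular DE framework.

BH adjustment is applied separately per contrast (statsmodels' step-up
implementation, cross-checked in the tests against a brute-force oracle).
The downstream filter is strict: baseMean > 100 normalized reads,
|log2FC| > 1, adjusted p < 0.05; boundary values are excluded.

## Survival

Kaplan–Meier, log-rank and Cox proportional-hazards estimation are delegated
to lifelines behind the package's contracts. Cox fits use Efron tie handling
by default (Breslow by config); categorical covariates are dummy-coded
against declared reference levels (`mid` for the stratum, `favorable` for
cytogenetic risk; first level alphabetically otherwise); age enters as a
continuous covariate. Records with missing survival covariates are dropped
with a logged count. Confidence intervals are exp(coef ± 1.96·se). A
partial-likelihood score test evaluated at zero is implemented directly and
used as a cross-check: for one binary covariate without ties it coincides
with the log-rank chi-square. Proportional-hazards diagnostics (Schoenfeld
residuals), competing risks and time-varying covariates are out of scope.

## Factor correlation and mutation association

Chromatin-factor expression is correlated with R/G ratios by Pearson's r
(two-sided p from the t reference with n−2 df), BH-adjusted across the panel.
The default 12-factor panel covers regulators of repeat chromatin
(POU5F2, ASH1L, BAZ2B, ATRX; SUV39H1, EHMT2, TRIM28, DAXX; SETDB1, CBX5,
DNMT1, CHAF1A); any user-supplied list is accepted, and factors absent from
the expression matrix are skipped with a warning. Mutation flags are tested
against ratios with the two-sided Wilcoxon rank-sum test: exact enumeration
when the smaller group has ≤ 8 samples and values are untied (the regime
where the clinically interesting associations occur), otherwise the
tie-corrected normal approximation with continuity correction.

## Synthetic cohorts

The generator emits count tables in the same dialect the readers consume,
plus metadata and a `truth` sidecar, and is first-class, tested code. Its
defaults define the study-like conditions used throughout the test suite:

* **Cohort**: 20 samples per planted group (low/mid/high), 2000 genes,
  810 repeats split SINE 250 / LINE 250 / LTR 150 / Satellite 40 / DNA 120.
* **Counts**: per-feature base means are log-normal (σ = 1.5), scaled so the
  expected library is 2×10⁶ reads with a 10% repeat share whose class
  composition matches the observed read fractions (SINE 40%, LINE 30%,
  LTR/ERV 9%, satellites 0.2%, DNA transposons the remainder). Counts are
  NB(μ, α) with dispersion α = 0.2 (typical between-patient bulk RNA-seq
  variability) and log-normal library factors (σ = 0.25).
* **Planted signal**: the whole repeat compartment of a sample is multiplied
  by its group factor 0.6 / 1.0 / 1.5. These scalings are generator defaults
  chosen to spread R/G ratios over a range comparable to real cohorts
  (≈0.82–1.32) after the default transform; they are tunable, not measured
  values.
* **Survival**: exponential event times with hazard h₀·exp(logHR·1[low]),
  h₀ = 1/1000 per day, logHR = ln 3 (low-repeat = worse prognosis),
  independent exponential censoring at 1/2500 per day (≈25–30% censoring).
* **Factors**: factor = mean + ρ·z + √(1−ρ²)·noise with z the standardized
  R/G signal, so the population Pearson correlation equals the tier target
  (0.8 / 0.4 / 0.0) exactly.
* **Mutations**: one binary flag with carrier probability 0.30 in the high
  group and 0.05 elsewhere, so the rank-sum stage is exercised end to end.

A single seed drives everything; per-stage sub-streams use fixed stream keys
(`default_rng([seed, stream])`) so a change in one stage's draw count does not
perturb the others. What the generator does **not** emulate: multimapper
ambiguity in repeat quantification, per-locus repeat structure, batch
effects, correlated gene modules, and non-proportional hazards. Passing tests
therefore demonstrate that the statistics recover planted structure under the
model's own assumptions — not that the biological signal in any real cohort
has this strength or shape.

## Numerical choices and degenerate inputs

* Even-length medians: mean of the central two, everywhere.
* `cut_interval` edge rule: right-closed bins, minimum included in bin 1;
  degenerate range → all `mid`.
* Dispersion floor 1e-8; features with zero variance and equal means get
  log2FC 0 and p 1 rather than NaN.
* Exact-vs-approximate rank-sum threshold: min group size 8, no ties.
* Cox: Newton-type optimization via lifelines with step size 0.95; constant
  covariates, empty risk information and fewer events than parameters are
  rejected with named errors before fitting.
* All tabular outputs are UTF-8 TSV with '.' decimal and `NA` for missing
  cells; floats are written with repr-stable formats so identical runs are
  byte-identical.

## Problem sizes in the validation suite

The test and acceptance simulations use the generator defaults (60-sample
cohorts) and statistically conventional replicate counts — 20 cohorts for
stratification concordance, 1000 features for DE calibration, 200 log-rank
and 500 Cox replicates, n = 120 for correlation-tier recovery — sizes at
which every Monte-Carlo band in the suite is comfortably narrower than the
tolerance it checks.

## Known limitations

* The DE surrogate adjusts for no covariates (no gender/batch terms) and
  performs no fold-change shrinkage; it is a calibrated two-group test only.
* One transform per run: cohorts normalized with different transforms should
  be stratified separately, and cross-cohort ratio comparability is not
  guaranteed.
* Real-cohort quantities (stratum counts, published survival p-values and
  hazard indices, dysregulated-repeat counts) depend on restricted patient
  data and are outside what the synthetic suite can or should reproduce.
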