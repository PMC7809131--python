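# Methods

This note documents the statistical models implemented in `exmirna`, the
design of the synthetic-data generator, the numerical choices made where
several defensible options existed, and the known limitations of both.

## Study design being modeled

The package targets a two-group prospective infant cohort: mothers who
drank heavily during pregnancy versus abstaining/light-drinking controls,
with infant plasma sampled at two postnatal ages (2 weeks and 6.5
months) and assayed on a 752-assay qPCR miRNA panel. Default sizes are
31 controls and 37 exposed. Exposure is quantified as ounces of absolute
alcohol per day (AA/day); maternal smoking (cigarettes/day) is the main
correlated co-exposure; outcomes are WHO growth z-scores
(weight/length/head circumference) and novelty preference on the Fagan
Test of Infant Intelligence (FTII, percent looking time at a novel face).

## QC and normalization

**Hemolysis.** Plasma miRNA content is easily contaminated by erythrocyte
miRNAs. A sample is excluded only when both indicators exceed their
thresholds: absorbance at 414 nm (free hemoglobin) strictly above 0.3 AU
and ΔCT(miR-23a-3p − miR-451a) strictly above 7 cycles (miR-451a is
erythrocyte-enriched, so a large gap marks contamination). Boundary
values pass. Detection of the erythrocyte transcript SLC4A1 is surfaced
as a warning, not an exclusion. Missing marker CTs leave the sample
retained with an indeterminate status.

**Detection filter.** A miRNA is "expressed" when detected in at least
80% of samples in at least one exposure-group × age cell (≥, so exactly
80% qualifies). Samples whose plate half failed amplification criteria
are structurally missing for those assays: they leave both the numerator
and the denominator of the detection rate and are never imputed.

**Non-detect imputation.** Within the expressed set, a non-detected
reaction is assigned the miRNA's maximum detected CT plus one cycle —
i.e. "just below the worst detected level" — pooling both groups and all
samples of a timepoint, since the rule is a property of the assay, not
of a group. The operation is idempotent.

**Global-mean ΔCT.** ΔCT = CT − (per-sample mean CT over the expressed
set after imputation). Per-sample ΔCT values are exactly mean-zero, the
transform is invariant to any per-sample additive shift (so plate-level
offsets cancel), and a unit difference corresponds to a twofold
expression difference with lower ΔCT = more expression. The open choice
of which assays enter the global mean is resolved as: the expressed set
after imputation.

## Effect-size screening

Group contrasts per miRNA come from an ANCOVA, ΔCT ~ group +
cigarettes/day, with adjusted means evaluated at the covariate grand
mean. Cohen's d uses the adjusted means in the numerator but the pooled
within-group SD of the raw ΔCT in the denominator (group SDs are the
reported descriptive quantity; covariate-residual SDs would shrink the
denominator and inflate d). Hedges' g applies J = 1 − 3/(4(n−2)−1). The
95% CI is the normal approximation d ± 1.96·SE with
SE = √((n_C+n_E)/(n_C·n_E) + d²/(2(n_C+n_E))); no noncentral-t
refinement is used. Screening keeps |d| ≥ 0.40 — justified by the
standard translations U3 = Φ(0.40) ≈ 66%, logistic odds ratio
exp(0.40·π/√3) ≈ 2.07, and a binomial effect-size display difference of
≈ 20 points — and no multiple-testing correction is applied: the screen
is an effect-size filter, not an inference; the subset whose CI excludes
zero is flagged separately.

The sex-stratified bootstrap resamples subjects with replacement within
exposure groups (preserving the 31/37 design), 2000 iterations each for
the combined sample, females only, and males only, re-running the ANCOVA
per iteration. A miRNA is called sex-specific when that sex's proportion
of significant iterations exceeds 0.5 and the combined-sample
proportion; strata under 4 subjects yield "indeterminate". The ANCOVA is
a closed-form least-squares kernel (one solve per iteration for all
miRNAs simultaneously); equivalence to `statsmodels` OLS is asserted in
the tests.

## Co-expression networks

Within each group, Pearson correlations between all expressed miRNA
pairs; p-values from the exact t transform with n−2 df; entries with
p ≥ 0.05 masked (unadjusted, matching the screening philosophy).
Matrices are ordered by complete-linkage hierarchical clustering on the
distance 1 − r. The count of significant pairs is the group's summary
statistic; its stability is assessed by a subject-level bootstrap with
percentile CIs (99% by default) and a mean ± SD band. Constant columns
give undefined correlations and are treated as non-significant with a
warning.

Chromosomal annotation comes from a miRBase-dialect GFF3 (`miRNA`
feature lines; MIMAT accession in `Alias`, name in `Name`); loci sharing
a MIMAT receive incrementing copy indices (the ".1" duplication
convention). A locus is "clustered" when another miRNA locus on the same
chromosome lies within 10 kb (interval gap). Cross-chromosome enrichment
counts significant pairs per unordered chromosome pair — a pair counts
once per chromosome-pair combination of its loci — normalizes by the
product of expressed-miRNA counts on the two chromosomes, and reports
the exposed/control fold change, flagging division by zero as infinite.
For the within/cross partition a pair is "within" when its locus sets
share a chromosome, so within + cross equals the total exactly.

## Confirmatory factor analysis

Model: Σ(θ) = ΛΦΛᵀ + Ψ, covariance structure only (no mean structure).
Identification fixes factor variances at 1 with all loadings free, so
factor covariances are correlations and are bounded to (−0.999, 0.999)
during optimization — without the bound the search can drift into
degenerate regions (φ ≫ 1 compensated by shrunken loadings) at small n.
Bifactor models add a general factor on all items, orthogonal to the
mutually orthogonal specific factors. Residual covariances are free only
for explicitly listed item pairs.

Estimation minimizes F = log|Σ| + tr(SΣ⁻¹) − log|S| − p by L-BFGS with
the analytic gradient (∂F/∂Σ = Σ⁻¹(Σ−S)Σ⁻¹ chained to each parameter
block), principal-axis-flavoured starting values, convergence tolerance
1e−8 on the discrepancy change, and up to 5 restarts with inflated
residual starts if the search stalls outside the positive-definite
region (non-PD trial points return a finite barrier value so the line
search can back off). χ² = (n−1)·F_min. Standard errors invert the
observed information, 2/(n−1)·H⁻¹ with H the central-finite-difference
Hessian of the analytic gradient. Heywood solutions (residual variance
< −1e−6) are flagged and count as non-converged in simulations.

Fit indices follow the standard definitions: CFI and TLI against the
independence (diagonal) baseline, RMSEA = √(max(χ²−df,0)/(df(n−1))) with
its CI from noncentral-χ² inversion, SRMR from the standardized residual
matrix; df = 0 models are perfect by convention. Information criteria:
AIC = −2LL + 2q, BIC = −2LL + q·ln n, SABIC with penalty ln((n+2)/24);
−2LL uses the (n−1)-scaled covariance likelihood, consistent with the χ²
convention, so comparisons between models fitted to the same data are
meaningful (absolute values differ from software that counts mean
parameters — degrees of freedom here never include intercepts).

**Bartlett correction.** For small samples the omnibus χ² is multiplied
by 1 − (4k + 2p + 5)/(6n), with k latent variables, p observed variables
and n the sample size plus one; the corrected statistic can re-enter the
descriptive indices on request (both baseline and target χ² are scaled).
At k=3, p=22, n=68 the factor is 0.850490 and 274.617 × 0.850490 =
233.56; published analyses of this configuration print 233.253, a
0.3-unit gap implying a slightly different effective n — the formula,
not the printed value, is the tested quantity.

**Reliability.** ω = (Σλ)²/((Σλ)² + ΣVar(ε) + 2Σcov(ε)) — residual
covariances enter the denominator so collinear residuals reduce ω — and
maximal reliability H = Σ(l²/(1−l²))/(1+Σ(l²/(1−l²))) on standardized
loadings, sign-invariant and never below the best item's l². Factor
scores for downstream models are unweighted means of each factor's item
ΔCTs (lower score = higher expression).

## Mediation

Single-mediator path model on standardized variables: mediator ~
exposure (a), outcome ~ exposure + mediator (c′, b); specific indirect
= a·b; total = c′ + a·b holds exactly for least squares on one sample.
The Sobel test uses the first-order delta SE √(a²SE_b² + b²SE_a²).
Smoking is treated as an exogenous variable correlated with exposure by
default (it does not enter the two regressions); a sensitivity switch
includes it as a covariate in both equations instead. The bootstrap CI
is bias-corrected (BC, not BCa): case resampling, z₀ from the fraction
of bootstrap estimates below the point estimate, percentile endpoints at
Φ(2z₀ ± 1.96). Missing outcomes are handled complete-case per model.
The battery runs three single-factor models per outcome plus a joint
model with all factors as simultaneous mediators in one outcome equation
(their residual association left free, the regression analogue of
residually correlated mediators).

A known property worth stating: at the joint null a = b = 0 the product
statistic is singular and *every* standard interval for a·b over-covers
(measured ≈ 0.995 here); near-nominal ≈ 95% coverage appears in the
regular case where only one path is zero. Tests assert both behaviors
rather than forcing 95% at the singular point.

## Monte Carlo power

CFA study: population model with standardized loadings 0.50, factor
correlations 0.50, residual variances 0.75, n = 59, items allocated
8/5/5 to three factors. Each replicate draws multivariate-normal data,
refits the model, and records per-parameter power (|z| > 1.96), 95%
Wald-interval coverage, and percentage bias; Heywood or failed
replicates are excluded and counted. The default 1000 replicates keep
the study under ~15 s on one CPU; 10,000 is available for full runs.

Observed at 1000 replicates: loading power ≈ 0.86–0.93, coverage ≈
0.91–0.95, |bias| < 3%, convergence ≈ 98%. Factor-covariance power is
≈ 0.69–0.80 — materially below the ≈ 0.91 sometimes quoted for designs
of this size. This is not an estimation defect: the exact asymptotic
Wald power computed from the Fisher information at the population values
is 0.782–0.854 under the 8/5/5 allocation (0.854 for the covariance of
the two largest factors), and a sensitivity sweep over plausible
17–18-item allocations tops out near 0.90 only for extreme splits
(8/7/3) that in turn push the weakest loading's power below its expected
band. Covariance power at n ≈ 59 is allocation-limited; the package
reports it honestly.

Mediation study: the standardized trivariate system with a = b = c′ =
0.40 at n = 58. The population is standardized by construction, so
replicates are fitted as-is (no per-sample re-z-scoring, which would
make the classical SEs conservative); intervals use the t critical value
of each equation's residual df, consistent with the t-based tests of the
least-squares fit; the indirect effect uses the delta-method SE.
Observed: path power ≈ 0.89–0.95, indirect power ≈ 0.72, coverage ≈
0.93–0.95, |bias| < 0.2%. Percentage bias is 100·(mean estimate −
truth)/truth and is undefined (reported as NaN) for zero-truth
parameters.

## Synthetic-data generator

The generator is first-class, tested code. Its defaults state the study
conditions: 31/37 groups, two timepoints, 752 assays of which 148 are
expressed, 18 exposure-responsive miRNAs driven by a 3-factor latent
structure (allocation 8/5/5, standardized loadings 0.5, factor
correlations 0.5), exposure effects spanning d = 0.4–0.9, non-detect
dropout 5%, and structural paths a = 0.4, b = −0.4, c′ = −0.4 linking
exposure, the first latent factor, and the growth/FTII outcomes on
standardized scales (exposure reduces growth directly and through the
factor). Smoking is zero-inflated Poisson with higher prevalence among
exposed mothers (0.80 vs 0.55, mean 6 cigarettes/day among smokers), so
the ANCOVA adjustment is non-trivial. Three independent RNG streams
(subjects, panel, hemolysis) derive from the seed, so generating one
block never perturbs another, and identical seed + config reproduce
byte-identical outputs.

CT model: expressed assays draw baselines uniformly in [18, 28] cycles
with within-group SDs in [0.8, 2.0]; responsive assays add −sd·(λ·f +
√(1−λ²)·noise) plus a group shift; a non-detect occurs when the latent
CT exceeds the detection ceiling of 37 cycles or by random dropout.
Baseline and SD ranges are chosen so the ceiling essentially never
censors expressed assays (real panels show SDs up to ~5.7 cycles, where
ceiling censoring would be material — a deliberate realism trade-off
that keeps "dropout rate zero ⇒ no missing expressed values" exact).
Non-expressed assays detect with probability < 0.15 and, when detected,
fall near the ceiling.

Because global-mean normalization subtracts the per-sample average CT,
it both dilutes group effects (by their average over the expressed set)
and shrinks within-group SDs (through the factor-induced covariance with
the average). The generator therefore defines configured effect sizes
*on the normalized ΔCT scale*: it computes the normalized-scale
within-group SD analytically from the generative covariance and solves
the assay-level shifts so that each responsive miRNA's standardized
group difference equals its configured d in expectation. A side effect
faithful to real data: with predominantly upregulated true effects, null
miRNAs acquire a small opposite-signed apparent shift (≈ 0.09 SD at the
defaults), exactly as global-mean normalization does in practice.

What the generator does **not** emulate: PCR chemistry and amplification
curves, plate-position and batch effects, heavy-tailed or skewed CT
noise, age-dependent changes in the expressed set, sex-specific true
effects, and correlation between hemolysis metrics and expression.
Passing tests therefore demonstrate correctness of the statistical
machinery under a linear-Gaussian latent structure, not robustness to
those real-data features.

## Numerical choices and degenerate inputs

- Hemolysis thresholds are strict inequalities; boundary samples pass.
- Detection threshold is inclusive (≥ 0.80).
- Constant miRNAs: correlations undefined → non-significant with warning;
  zero-variance ANCOVA covariate → unadjusted means with warning;
  zero-variance mediation variables → error.
- d/g require n ≥ 2 and positive SDs per group; ΔΔCT requires both groups.
- CFA: non-PD trial covariances get a finite barrier; df < 0 raises;
  singular information → SEs reported as NaN with a warning.
- Bootstrap resampling is always seeded; degenerate resamples (constant
  columns) are skipped and logged in the mediation bootstrap.
- BC interval proportions are clipped to (1/(B+1), 1−1/(B+1)) before the
  normal inversion so z₀ stays finite.

## Limitations

- The CFA engine is covariance-only ML: no mean structure, no missing-data
  FIML, no ordinal/WLSMV estimation, no exploratory rotation.
- Effect-size CIs are normal-approximation, not noncentral-t.
- Correlation-network inference uses unadjusted p-values by design.
- The mediation module is single-level and cross-sectional; no
  longitudinal or causal-sensitivity machinery.
- Degrees-of-freedom bookkeeping excludes mean parameters, so information
  criteria are comparable within this package but offset from software
  that counts intercepts.
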