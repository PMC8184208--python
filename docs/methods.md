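# Methods

## Observation model and the synthetic cohort

The generator (`pagetmeth.synthetic`) emulates a two-group blood
methylation study on an Infinium 450K-style array, split into a discovery
and a cross-validation cohort of 116 cases / 130 controls each (the
default study design). Each probe has a baseline M value drawn from a
bimodal mixture (30% unmethylated around M ≈ −2.5, 30% methylated around
M ≈ +2.5, 40% intermediate), matching the characteristic two-hump beta
distribution of whole-blood 450K data. Measurement noise is Gaussian on
the M scale (`noise_sd`, default 0.5). Betas are the base-2 logistic of
M, and signal intensities are `meth = β·T`, `unmeth = (1−β)·T` for a
lognormal total intensity T (log2 median 13 by default, configurable so
the intensity QC filter can be triggered on demand), so the standard
M-value formula recovers the simulated value up to the +1 offsets.

Planted case/control effects are specified on the beta scale
(`delta_beta = β_case − β_control`). A plain logit-derivative conversion
to an M-scale shift would under-deliver the target difference because the
logistic is averaged over the noise distribution (Jensen attenuation);
instead the generator solves
`E[logistic2(m₀ + d + ε)] − E[logistic2(m₀ + ε)] = Δβ` for the shift `d`
by Gauss–Hermite quadrature and bisection, so the *realized* group
difference is calibrated in expectation. Planted probes are given
intermediate baselines (m₀ ~ N(0, 0.5)) so beta-scale effects of the
configured magnitude are realizable. The calibration is verified over 20
replicate seeds in the test suite.

Confounder structure: age (group-specific means), sex (group-specific
male proportions, with a small M shift on a random probe subset), a
bisulfite-batch shift on 5% of probes, an array assignment (12 samples
per slide), and an 8-part blood cell mixture (CD14 monocytes, CD19 B,
CD4 T, CD56 NK, CD8 T, eosinophils, granulocytes, neutrophils) drawn from
group-specific Dirichlet distributions. A configurable number of
"cell-informative" probes take their per-sample beta from the mixture of
sorted-cell reference profiles (one cell type high, others low), which is
what makes reference-based deconvolution work on the simulated cohort and
exactly what it cannot capture about real data: real cell-type signatures
are correlated across probes and imperfectly characterized, so passing
deconvolution tests here demonstrates correctness of the estimator, not
field performance. Likewise the generator draws probe noise independently
(an optional within-region correlation parameter exists, default 0,
because the within-region correlation of neighboring CpGs is not
something we wanted to assert); real neighboring CpGs are correlated, so
region-test power on real data will differ from the simulated power.

Exclusion-flag categories (cross-reactive, SNP within 3 bp, smoking-
associated) are drawn on disjoint probe sets so configured counts are
exact; overlapping flags are still handled by the filter's first-match
accounting when present in externally supplied manifests.

## Quality control

Samples are excluded when log2 of the median methylated *or*
unmethylated raw intensity falls below 11.0 (450K QC convention for the
"median intensity < 11" rule), then on reported/predicted sex mismatch;
missing reported sex excludes the sample explicitly rather than passing
it. Sex is predicted from mean X-chromosome beta against a threshold
(default 0.4) — a deliberately simple stand-in needed only to exercise
the filter. Probes are excluded, with first-match category accounting and
exact count conservation, in the order: detection failure (detection
p > 0.05 in more than 5% of samples — the aggregation rule is a
documented choice, proportion configurable), cross-reactive flag, SNP
flag, sex chromosome, smoking list. Between/within-array normalization is
a rank-mean quantile normalization (switchable to none); it replaces
chemistry-aware normalization, which needs raw two-channel data the
pipeline does not model.

Cell composition is estimated by nonnegative least squares of each
sample's betas on the sorted-cell reference over a discriminating probe
subset (default: top 100 probes per cell type by between-type range),
i.e. the reference-based deconvolution contract (profiles in, fractions
out) without the original full estimation machinery. Surrogate variables
are the top-k principal components (default k = 10) of the residual after
projecting out the known covariates and the phenotype; the components are
orthogonal to every covariate by construction. This is a deliberate
simplification of iterative surrogate-variable estimation: the
"significance" selection of components is not reproduced.

## Site-level analysis

Per-probe OLS of M on phenotype plus confounders; the design is checked
for full rank and collinear columns are named in the error. Variance
moderation follows the standard empirical-Bayes method-of-moments on log
sample variances, including the closed-form trigamma inversion for the
prior df; the degenerate branch (observed spread of log-variances within
sampling noise) uses an infinite prior df with the pooled mean variance
as prior, matching the reference implementation of this estimator.
Reported effect sizes are the *raw* control-minus-case group mean
difference on the beta scale (negative = hypermethylated in cases),
alongside the M-scale model coefficient — the table convention of the
field; whether published Δβ tables are raw or covariate-adjusted is
ambiguous, and the raw difference matches the literal footnote formula.

Replication is two-stage: BH FDR < 0.05 in discovery, then BH over the
cross-validation p-values *of that subset only* (configurable to
genome-wide). Meta-analysis is inverse-variance fixed-effect with normal
p-values; DerSimonian–Laird random effects is available behind a flag.
The pipeline feeds the per-stage M-scale coefficients and moderated
standard errors into the meta-analysis; the `se_from_p` normal-quantile
back-out exists to reproduce published table arithmetic from printed
effect/p pairs.

## Region-level analysis

Regions come from the manifest: islands by island id, promoters = TSS200/
TSS1500 probes grouped by gene, gene bodies = 5'UTR/Body probes grouped
by gene (a probe with such a feature but no gene symbol is skipped and
counted). The test fits both logistic models by IRLS with a ridge penalty
of 1e-6 on non-intercept coefficients — numerical stabilization only, for
regions whose site count approaches the sample count; no site
pre-screening is done, all n sites enter. Perfect separation is detected
(diverging coefficients, or a ridge-capped fit that classifies every
sample exactly) and returned as a flagged non-converged result with p
recorded as missing, never p = 0. Single-site regions are tested with
df = 1. The degenerate zero-site region returns χ² = 0, df = 0, p = 1.

The discovery→cross-validation workflow mirrors the site analysis: BH
over all converged regions of a type selects regions for CV testing; CV
BH runs over that subset. The family-wise track applies Bonferroni over
all discovery regions of the type and then Bonferroni of the CV p-values
over the discovery-Bonferroni-significant subset. "Selected" regions for
site extraction default to the discovery-FDR set (a flag switches to
replicated-only); within each selected region, BH over that region's own
site p-values (from the full model's Wald tests) marks important sites.
Pooled sites are the de-duplicated union of discovery-significant sites
and the within-region important sites, with multi-tag provenance
(`dms`, `dmr_island`, `dmr_gene_body`, `dmr_promoter`) so either reading
of the pooling recipe can be reconstructed.

## Classification

OPLS-DA: unit-variance scaling and mean centering (the SIMCA default),
removal of `n_ortho` label-orthogonal components (default 1 — published
score plots show one predictive versus one orthogonal component;
configurable), then one predictive PLS component. Prediction applies the
training centering/scaling, deflates by the stored orthogonal components,
and projects on the unit predictive weight vector. `n_ortho = 0` reduces
exactly to single-component PLS1. Evaluation: Mann–Whitney AUC with ties
counted ½; sensitivity/specificity at a threshold equal to the median of
the evaluated scores (configurable to the training median).

Elastic-net subset selection: penalized binomial regression at mixing
0.5 (configurable), lambda chosen on a log grid spanning two decades
below the analytic lambda-max by 10-fold cross-validated binomial
deviance with the one-standard-error rule; features are re-standardized
inside each training fold so the lambda choice sees no leakage. The
selection behavior was cross-checked against the R reference
implementation of this estimator: on seeds whose CV deviance curve is
flat near its minimum, both admit noise features well above the typical
rate, so tests bound the median rather than every seed. The effect-size
comparison between the selected subset and the remaining pooled sites is
a two-sided Wilcoxon rank-sum on |Δβ| (robust to the skew of absolute
methylation differences; Welch t behind a flag).

## Network

Partial correlations among pooled sites use a shrinkage-regularized
correlation matrix — convex combination with the identity at the analytic
Schäfer–Strimmer intensity — inverted to a precision matrix, with
`pcor_ij = −Ω_ij/√(Ω_ii Ω_jj)`. How the original analysis inverted a
system with far more sites than samples is not recoverable; the shrinkage
estimator is a documented substitute with the same contract. P-values use
the Fisher z transform with effective sample size `n − (k−2) − 3`; when
that is not positive (site count near the sample count) p-values are
reported as missing with a warning rather than fabricated. Significance
defaults to BH q < 0.05 over all pairs (raw p < 0.05 behind a flag).

Keyword edges: for two keywords, cross pairs have one site annotated to
each (via probe→gene→keyword; probes without gene annotation drop out),
pairs internal to either keyword are excluded, and all remaining
pooled-site pairs are background. The 2×2 table of pair class ×
partial-correlation significance is tested by two-sided Fisher exact;
BH runs over all keyword pairs and edges with q < 0.05 *and* odds ratio
> 1 are kept — the two-sided p also fires on significant depletion of
cross-keyword correlations, which is not functional relatedness.

## Numerical choices and problem sizes

Logistic IRLS: convergence when the deviance change is below 1e-10
relative and the max coefficient step below 1e-6; linear predictors
clipped at ±30; weights floored at 1e-10. Quantile normalization averages
the reference distribution across ties. NNLS deconvolution is exact for
noiseless mixtures; weights optionally renormalized to sum to one.
BH q-values are the standard step-up; Bonferroni adjustments cap at 1.
All randomness derives from one configuration seed through named
substreams, so the manifest and cohort are independently regenerable and
full runs are checksum-reproducible.

Test and demonstration scales are chosen to exercise every code path at
desk scale: cohorts of 492 samples (the default split sizes) over 400–
2,000 probes, 1,000-replicate null calibrations, 20–25-seed power and
calibration loops, and a single array-scale (485,512-probe) manifest for
the filter-ledger arithmetic. The array-scale cohort itself (hundreds of
thousands of probes × hundreds of samples) is intentionally not simulated
in tests; nothing in the implementation depends on probe count beyond
linear scaling.

## Known limitations

- No raw two-channel (IDAT) modeling, probe-type chemistry, or
  chemistry-aware normalization; the quantile stand-in changes only ranks.
- The sex predictor is a threshold on mean X beta, not a calibrated
  classifier.
- Surrogate variables are residual PCs; they do not protect the phenotype
  coefficient from variance absorbed by genuinely phenotype-correlated
  structure the way iterative reweighting schemes attempt to.
- Fisher-z p-values for partial correlations are unavailable when the
  site count approaches the sample count; the network stage is meant for
  pooled-site sets well below the cohort size.
- The cohort-arithmetic of real studies can include exclusion categories
  beyond those modeled; the ledger surfaces any extra category explicitly
  rather than hiding it.
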