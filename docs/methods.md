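# Methods

## The two-sample MR model

Each SNP j used as an instrument has a true per-allele effect γ_j on the
standardised exposure (birth weight, SD units) and — under the
instrumental-variable assumptions — an effect θ·γ_j on the log-odds of
the binary outcome (breast cancer), where θ is the causal log-odds ratio
per 1-SD higher exposure. Observed summary statistics are treated as
normally distributed around these values with known standard errors.
Horizontal pleiotropy enters as an additive per-SNP effect α_j on the
outcome, so the generative model behind both the estimators and the
synthetic-data module is

    β̂_Xj ~ N(γ_j, σ²_Xj),    β̂_Yj ~ N(θ·γ_j + α_j, σ²_Yj).

The five univariable estimators differ in which α-configurations they
tolerate: IVW requires all α_j = 0; the weighted median tolerates <50% of
weight from invalid SNPs; the weighted mode requires only that the
largest cluster of Wald ratios is valid; MR-Egger requires α independent
of γ (InSIDE) and estimates mean(α) as its intercept; penalised robust
IVW tolerates a minority of gross outliers.

## Harmonisation

Outcome and covariate records are expressed on the exposure's effect
allele (swapped alleles flip the beta sign and complement the allele
frequency) and every record is then oriented to the exposure-increasing
allele, flipping all betas jointly; Wald ratios are invariant to this
orientation. Strand-ambiguous (A/T, C/G) SNPs are aligned by allele
letters alone because the intended inputs are curated lead-SNP tables
that are already strand-matched; a strict mode that drops palindromic
SNPs with allele frequency in [0.42, 0.58] exists but is off by default.
Loci absent from a dataset may be represented by a proxy SNP from a
user-supplied lead→(proxy, r²) map, with r² floors of 0.6 (univariable)
and 0.8 (multivariable) by default; proxy alleles are taken as reported,
since curated proxy tables are phase-matched to their leads. Low
imputation quality does not filter by default (an optional floor exists).

## Estimation details and numerical choices

- **Weights.** All inverse-variance weights use the outcome-side variance
  only (first-order Wald SE σ_Yj/|β̂_Xj|); a second-order option adds the
  exposure-side term and is used for simulator cross-checks.
- **Random effects.** The multiplicative model multiplies the
  fixed-effects SE by √(Q/df) floored at 1 (df = L−1 for IVW, L−2 for
  Egger, L−K for MVMR-IVW, L−K−1 for MVMR-Egger). The floor means a
  random-effects SE is never smaller than the fixed-effects SE.
- **Intervals and p-values.** 95% CIs are normal-theory β ± 1.96·SE for
  every method (Egger can optionally use t critical values); p-values are
  two-sided normal except the Egger slope/intercept terms, which use t
  with the residual df.
- **Weighted median.** Ratios are sorted lexicographically by (ratio,
  weight) so tied ratios have a canonical order; the estimate
  interpolates ratio against cumulative midpoint weight at 0.5.
- **Weighted mode.** Bandwidth = factor × 0.9·min(sd, normal-scaled
  MAD)·L^(−1/5) on the ratios (factor default 1; 0.5/2 useful as
  sensitivity settings); the density argmax is located on a 1024-point
  grid spanning the ratios ± 3 bandwidths and refined on a 201-point
  local grid. Identical ratios (zero bandwidth) return the common ratio.
- **Bootstrap.** Median/mode SEs come from a parametric bootstrap
  (resampling both betas from their sampling normals), default 5,000
  draws with an explicit seed; SEs are stable to about two significant
  figures at that size. `n_boot=0` skips the bootstrap for simulation
  loops that only need point estimates.
- **Penalised robust IVW.** Each SNP's Q contribution is referred to
  chi-square(1); its weight is multiplied by min(1, p_j/0.05)
  (equivalently min(1, 20·p_j), the conventional penalty), then a Tukey
  biweight fit (c = 4.685, 95% efficiency under normality) through the
  origin is run with the penalised weights. The SE is floored at the
  fixed-effects IVW SE; failure of the robust fit falls back to the
  penalised non-robust IVW with a logged warning.
- **Stepwise Q-pruning.** Greedy: remove the largest per-SNP Q
  contributor (ties broken by lexicographically smallest SNP id), refit,
  repeat until the Q p-value ≥ 0.05. A non-refitting variant (ranking
  against the original pooled estimate) is available; greedy-refit is the
  default. Pruning below two instruments reports non-convergence.
- **Influence measures** are computed on the zero-intercept weighted
  regression that defines IVW (transformed scale x* = β̂_X/σ_Y,
  y* = β̂_Y/σ_Y), so flags refer to the estimator actually reported:
  Cook's distance with threshold 4/L, externally studentised residuals
  with threshold ±2.
- **r² from p-values.** The per-SNP 1-df F statistic is recovered through
  the exact identity F(1, ν) = t(ν)², which remains finite far into the
  tail where the direct F-quantile overflows; p-values ≤ 1e-300 are
  clipped with a warning.
- **Degenerate inputs.** A single instrument degrades IVW to its Wald
  ratio; zero exposure betas are excluded as null instruments; exact-fit
  data give zero Q, zero Cook's distances and zero studentised residuals;
  a rank-deficient MVMR design aborts naming the collinear columns.

## The synthetic-data generator

The generator emulates the study's scale by default: 41 independent
loci, MAF uniform on (0.05, 0.5), per-SNP exposure effects scaled so the
instrument explains r² = 1.3% of the exposure, exposure GWAS n = 143,677,
outcome GWAS 122,977 cases / 105,974 controls, true θ = ln 0.86.
Summary-level SEs use σ_X = 1/√(2f(1−f)n) for a standardised trait and
σ_Y = √(N/(2f(1−f)·n_ca·n_co)) for a log-odds outcome. Pleiotropy
architectures: none, balanced (mean-zero α), directional (nonzero mean;
InSIDE holds), and InSIDE-violating (α correlated with γ). Latent effects
are drawn once per spec and held fixed across replicates so replicate
variation isolates sampling noise; a fully random mode redraws them. A
fraction of outcome rows (default 0.3) is emitted on the swapped allele
so harmonisation is exercised end to end.

What it does **not** emulate: linkage disequilibrium between instruments
(the intended instruments are independent loci), sample overlap between
the two GWASs, allele-frequency differences between datasets, binary-trait
non-collapsibility (outcome statistics are generated directly on the
log-odds scale; a slow individual-level mode with genotype sampling
exists for small-n cross-checks against two-stage least squares), and
winner's-curse in instrument discovery. Passing tests therefore validate
the estimators under the two-sample summary model's own assumptions, not
against every artefact of real GWAS data.

## Validation studies and problem sizes

The test suite validates each estimator against an independent
brute-force oracle (direct matrix solves for the weighted regressions,
hand-enumerated interpolation for the median, explicit density summation
for the mode, refit formulas for the influence measures) and by
simulation: parameter recovery over 500 replicates at the default study
scale, type-I error of the IVW and Q tests over 1,000 replicates,
planted-outlier detection, and recovery of a planted directional
pleiotropy mean over 200 replicates. The bundled analysis scripts use 300
replicates for their calibration tables. These sizes give Monte-Carlo
standard errors a few times smaller than the effects being checked while
keeping the whole suite desk-scale.

A known finite-sample effect visible in the calibration study: with
noisy exposure betas the MR-Egger slope is attenuated toward zero
(violation of the no-measurement-error assumption; the attenuation grows
as the between-SNP spread of γ shrinks relative to σ_X). At the default
study scale the attenuation is within Monte-Carlo error at 500
replicates, but for weaker instruments it is not, and the Egger estimate
should be read accordingly.

## Open design points

- The stepwise "model selection" routine is specified here as greedy
  removal of the largest Q contributor with refitting, the natural greedy
  reading of a stepwise-downward procedure; the alternative non-refit
  ranking is implemented for comparison.
- Pleiotropy filters are applied to whichever record represents a locus
  (lead or proxy), and the filter log records which was used.
- Covariate traits supplying only p-values participate in instrument
  filtering but are excluded from the MVMR design matrix.
- The reproduction entry point for the published per-SNP workbook
  resolves sheet layouts tolerantly (title rows, header synonyms,
  outcome-suffixed columns); it requires a local copy of the workbook and
  performs no download. The ER-positive/ER-negative and type 2 diabetes
  positive-control analyses are likewise reproducible only with their
  respective summary statistics; the pipeline itself is outcome-agnostic
  and is exercised on synthetic outcomes at all three subtype scales.
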