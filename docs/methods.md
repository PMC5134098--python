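# Methods

## The question and the model

`sexgencor` asks whether the common-SNP genetic control of a gene's
expression is the same in males and females.  Expression of one probe is
treated as two traits — one measured in males, one in females, on disjoint
samples — and the cross-sex genetic correlation

r_G = cov(g_m, g_f) / sqrt(var(g_m) · var(g_f))

is estimated per probe by bivariate GREML.  With samples stacked (males, then
females) and A the SNP-derived genomic relatedness matrix (GRM), the
phenotypic covariance is

V = σ²_gm·B_m + σ²_gf·B_f + σ_gmgf·B_mf + σ²_em·D_m + σ²_ef·D_f,

where B_m, B_f are A masked to the within-sex blocks, B_mf is A masked to the
male-female cross blocks, and D_m, D_f are sex-indicator diagonals.  Fixed
effects are sex-specific means plus (optionally) covariates with sex-specific
coefficients — in particular neutrophil/lymphocyte/monocyte proportions for
the cell-adjusted analysis.  Per-sex heritability is h²_s = σ²_gs/(σ²_gs +
σ²_es).

Assumptions: additive polygenic effects captured by genotyped SNPs; Gaussian
residuals independent across individuals; unrelated (or weakly related)
samples; expression already variance-stabilised upstream.

## Estimation

Restricted maximum likelihood, maximised by average-information (AI) updates:

* score ∂l/∂θ_k = −½[tr(P V̇_k) − y′P V̇_k P y], AI_kl = ½ y′P V̇_k P V̇_l P y,
  with P the REML projection matrix;
* 3 EM-REML warm-up iterations for the linear (5-parameter)
  parameterisations; every proposed step — full AI, AI reduced to the
  components not blocked by a constraint, EM — is guarded by likelihood
  step-halving, so the accepted log-likelihood sequence is non-decreasing
  (up to ~1e-9 relative recomputation noise);
* start values: σ²_g = σ²_e = half the per-sex phenotypic variance, genetic
  covariance ¼·sqrt(σ²_gm σ²_gf);
* convergence: relative log-likelihood change < 1e-8, cap 100 iterations;
  fits that do not converge are flagged and excluded from panel summaries
  (and counted), not repaired;
* variance floor 1e-6 × phenotypic variance; components at the floor are held
  and the AI system reduced to the free components.

Three modes:

* **constrained** — variances ≥ floor and |σ_gmgf| ≤ sqrt(σ²_gm σ²_gf) by
  boundary projection, so |r̂_G| ≤ 1.  Because a projected search can stall
  on the |r_G| = 1 boundary below the boundary's own maximum, a fit ending on
  (or failing near) the boundary is refit in the tied 4-parameter
  boundary model (below) and the 5-parameter search restarted from that
  point; the better likelihood wins.  This makes the constrained maximum
  exact on both sides of the boundary.
* **unconstrained** — parameters free apart from positive-definiteness of V
  (enforced by step-halving), so r̂_G may leave [−1, 1]; this is the
  unbiased-estimate analysis.
* **rg_fixed_1** — the null for the boundary test, parameterised as
  (γ_m, γ_f, σ²_em, σ²_ef) with σ²_gs = γ_s² and σ_gmgf = γ_m γ_f, which
  traverses exactly the r_G = 1 surface.

The SE of r̂_G is the delta method applied to the inverse AI matrix.
r̂_G is reported as NA ("no genetic variance") when either genetic variance
lands at the floor or below 1% of that sex's phenotypic variance — the
correlation is numerically unidentifiable there.

## The boundary likelihood-ratio test

H₀: r_G = 1 lies on the edge of the constrained parameter space, so the LRT
statistic is distributed under H₀ as a 50:50 mixture of a point mass at 0 and
χ²₁.  The p-value is 0.5 at a statistic of 0 and ½·S_χ²₁ above it; for the
unconstrained analysis a plain χ²₁ p-value is used instead.  A constrained
fit that ends on the +1 boundary shares its parameter space with the null, so
its statistic is exactly 0 by construction; values below 1e-4 (well under the
χ²₁ noise floor, which carries ≈0.8% of null mass below that point) are
clamped to 0 so optimizer noise cannot leak out of the point mass.

## Dimorphism test

Mean expression difference by sex is tested per probe with y = a + Xb + g +
e, cov(g) = A σ²_g, cov(e) = I σ²_e (the same REML engine in univariate
mode), sex coded male 0 / female 1, cohort indicators as fixed effects when
given.  b̂ and its SE are GLS at the REML variance estimates; significance is
the Wald statistic (b̂/SE)² against χ²₁.

## Genotype QC and the GRM

SNPs with minor-allele frequency < 0.01 or Hardy-Weinberg exact-test
p < 1e-6 are excluded (the plain, not mid-p, exact conditional test).  The
GRM is the GCTA-style average over SNPs of products of standardized dosages
(x − 2p)/sqrt(2p(1−p)), allele frequencies estimated in the analysis sample,
missing dosages mean-imputed (zero after centering), uniform SNP weights.

## Expression preprocessing

Quantile normalization equalises each sample's value multiset to the mean
order statistics (ties receive the mean of the reference values they span;
exact idempotence therefore holds only for tie-free data).  The rank-based
inverse-normal transform maps to Φ⁻¹((rank − 0.5)/n) with average ranks for
ties, applied within sex × cohort groups before the bivariate analysis so
that unequal sex proportions cannot masquerade as genetic differences.
Residualization on covariates or expression PCs is ordinary least squares per
probe; each PC is first screened with a two-sample t-test across the sexes
(default threshold 0.05/k) and sex-confounded PCs are excluded from
residualization.  Probes are dropped when cross-hybridising to a sex
chromosome (alignment with ≥ 90% identity, ≥ 40 of 50 matching bases and no
gaps), flagged as background/uncharacterised upstream, on X or Y, or with
heritability not strictly above 10%; excluded probes are tallied once each
under the first applicable reason in that fixed order.

## Panel summaries

Bonferroni threshold α/m over input probes; significance is strict (p equal
to the threshold does not count).  QQ coordinates use the declared null's
quantiles, so the mixture null produces the leading plateau of p = 0.5.
Genomic-control λ maps p-values through the declared null's inverse survival
to χ²-equivalents; for the χ²₁ null, λ is the usual median ratio.  For the
mixture null the median equivalent is degenerate (the null median sits inside
the point mass at 0), so λ is taken at the 75th percentile, whose null value
equals the χ²₁ median (0.4549) — under the null both conventions give λ = 1.
Top-table ties in p are broken by |1 − r̂_G| descending, then probe id.

## The synthetic-data generator

Genotypes: dosage ~ Binomial(2, p) at Hardy-Weinberg proportions with
p ~ Uniform(maf_range), default MAF range [0.01, 0.5]; no linkage
disequilibrium.  An optional full-sib mode draws pairs from shared parental
haplotypes (independent transmissions per SNP) to mimic a mixed
pedigree/unrelated design; the default is unrelated individuals.

Expression, per probe: a shared causal set (default: all SNPs) carries per-sex
effect vectors drawn from a bivariate normal with correlation rg_true —
exactly equal at rg_true = 1, so the boundary null is exact.  Genetic values
are formed on standardized genotypes, and genetic values and residuals are
rescaled within sex so the realized heritability equals its target exactly
(sharper recovery tests at moderate n); scaling is around each group's own
mean, so between-sex mean noise survives and the dimorphism test's null stays
calibrated.  A constant sex_effect is added to females.  Optional blood
cell-type proportions come from a Dirichlet(15, 8, 2) scaled to 0.97 (typical
neutrophil/lymphocyte/monocyte composition) with user-chosen linear effects.

What the generator does not emulate: LD structure, imputation error, probe
intensity heteroskedasticity, batch structure beyond generic covariates, and
X/Y expression.  Passing tests therefore demonstrate correctness of the
estimator and its calibration under the model's own assumptions, not
robustness to those real-data features.

## Simulation sizes used by the test suite

Chosen so the full suite and the reproduction script each run in minutes on
one core, while keeping every check statistically meaningful:

* boundary-null calibration: 400 independent probes — each with its own
  genotype draw, so the zero-LRT fraction carries a plain binomial envelope —
  at 200 males + 200 females, 500 SNPs, h² = 0.5 per sex, true r_G = 1; the
  boundary fraction and the median constrained r̂_G (1.00) are read from this
  study.  Note the 50:50 point-mass weight is an asymptotic result: at this
  per-component information (se(σ̂²_g) ≈ √(2M)/n ≈ 0.16) the concavity of
  the √(σ̂²_gm σ̂²_gf) denominator pushes the empirical zero fraction a few
  points above 50% (it returns to ≈52% at M = 100, where the relatedness is
  more informative);
* parameter recovery: truth grid r_G ∈ {0, 0.36, 0.5, 1} × h² ∈
  {0.3, 0.68/0.64}, 250 per sex, 100 SNPs, 50 replicates per cell; the mean
  of converged unconstrained (unbiased) estimates must sit within 2 standard
  errors of the truth.  The SNP count is chosen so the finite-sample ratio
  bias of r̂_G (order M/n²) is far below the 2-SE resolution — at this size
  the check measures estimator correctness rather than the known
  small-sample bias of a correlation ratio;
* brute-force oracle: 20 instances of 10 + 10 samples × 40 SNPs; the fitted
  constrained log-likelihood must reach the maximum of a dense grid over the
  five components (step 0.05 on the unit-variance scale, per-sex total
  variance within [0.55, 1.45], covariance within the positive-definite
  bound) to within 1e-3;
* dimorphism null calibration: 400 probes at 60 + 60 samples × 150 SNPs,
  Kolmogorov-Smirnov test of p-value uniformity.

## Known limitations

* No X/Y models, no per-SNP genotype-by-sex scans, no Haseman-Elston or
  method-of-moments alternatives.
* The unconstrained r̂_G is a heavy-tailed ratio at low heritability or small
  n; means over few replicates are noisy there.
* Variance stabilisation (vsn) and probe detection p-values are upstream
  concerns; the generator emits post-stabilisation intensities.
* The heritability estimates feeding the 10% probe filter come from the
  univariate REML fit on the pooled sample; other estimators would shift the
  retained set.
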