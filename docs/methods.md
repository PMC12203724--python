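# Methods

## Estimands and estimators

Write \(G\) for a child's dosage of an effect allele (0/1/2) at one SNP,
and define three population regression coefficients on child genotype:
\(\beta_{CG\_CP}\) (child phenotype), \(\beta_{CG\_MP}\) (maternal
phenotype), \(\beta_{CG\_FP}\) (paternal phenotype). Under random mating
and Mendelian transmission, \(\mathrm{cov}(G_{child}, G_{parent}) =
\tfrac12\mathrm{var}(G)\), so a parental own-genotype effect \(b\)
appears in the child-genotype regression as \(b/2\); a parental indirect
(dynastic) effect \(d\) on the child appears in the child regression as
\(d/2\).

Two per-SNP estimators of \(\beta_{CG\_FP}\) from the (CP, MP) pair are
implemented exactly as their defining formulas:

1. **Subtraction**: \(\hat\beta_{CP} - \hat\beta_{MP}\), with naive SE
   \(\sqrt{v_{CP}+v_{MP}}\) (valid only for independent estimates) and
   corrected SE \(\sqrt{v_{CP}+v_{MP}-2\,\mathrm{cov}}\).
2. **IVW combination** of \(0.5\hat\beta_{CP}\) (weight \(w_1=4/v_{CP}\))
   and \(\hat\beta_{MP}\) (weight \(w_2=1/v_{MP}\)):
   \(\hat\beta = (0.5 w_1 \hat\beta_{CP} + w_2\hat\beta_{MP})/(w_1+w_2)\),
   with SE \(\sqrt{(0.5w_1/S)^2 v_{CP} + (w_2/S)^2 v_{MP} +
   \mathrm{cov}\,w_1 w_2/S^2}\), \(S=w_1+w_2\). The cross term equals the
   standard \(2ab\,\mathrm{cov}\) for the combination coefficients
   \(a=0.5w_1/S\), \(b=w_2/S\) (the \(2\times0.5\) cancels), and at
   \(\mathrm{cov}=0\) the variance reduces to \(1/(w_1+w_2)\), which is
   never larger than either component's variance — the efficiency claim
   is an algebraic identity, checked numerically in the tests.

Both estimators assume genetic effects equal across sexes and
generations, the same measurement scale in both regressions, random
mating, no parental indirect effects, and no stratification. The
simulator can violate each assumption on demand.

The coefficient covariance is modelled as one genome-wide scalar times
the per-SNP SE product: \(\mathrm{cov} = \widehat{int}\cdot
\mathrm{se}_{CP}\mathrm{se}_{MP}\), \(\widehat{int} =
\frac{N_S}{\sqrt{N_{CP}N_{MP}}}\rho\), where \(N_S\) is the effective
sample overlap and \(\rho\) the mother–child phenotype correlation. The
intercept may instead be supplied directly (as it would come from
bivariate LD-score regression on real data); supplying both requires
agreement to 1e-9. \(N_S\) is a user-supplied scalar; the package does
not resolve how related-but-not-identical individuals contribute to it.
Estimating the intercept by actual LD-score regression over LD-structured
genomes is out of scope: simulated SNPs are independent, so the intercept
form needs no LD machinery.

Because derived records feed downstream tools that expect an N column,
derived sets record an effective sample size: \(\min(N_{CP}, N_{MP})\)
for subtraction, and for IVW the precision-sum convention
\(N_{MP}(w_1+w_2)v_{MP}\) (the maternal-regression size at which a single
regression would match the combined precision). Both are conventions, not
estimands, and are recorded in provenance.

## The trio simulator

Parents are drawn in Hardy–Weinberg equilibrium at per-SNP effect-allele
frequency \(p \in (0.01, 0.5)\); mating is random; each parent transmits
one allele with probability dosage/2 (exact Mendelian transmission —
consistency is asserted at 100% of family–SNP pairs). SNPs are
independent loci: every formula under study is per-SNP and the intercept
covariance form needs no LD at this scale. Phenotypes are additive,

\(P = \textstyle\sum_j \beta_j G_j\; (+\sum_j d_{m,j} G_{m,j} + d_{f,j} G_{f,j}
\text{ for children}) + e\),

with unit-variance Gaussian residuals, so effects are in residual-SD
units; the mother's and child's residuals are jointly Gaussian with
correlation `rho_resid`. Child sex is Bernoulli(0.5) and affects effect
size only. An optional outcome phenotype \(Y = \theta P + e_Y\) per
person supports the MR demonstrations. Everything is reproducible from a
mandatory integer seed.

Default study conditions: 20,000 families, 100 SNPs, allele frequency
0.3, per-SNP effect 0.1 (genetic variance ≈ 0.42·100·0.01 ≈ 0.3 of the
unit residual variance — a strongly heritable trait with individually
modest loci), 500 replicates in the comparison grid. Smaller sizes are
used where a computation needs many replicates (2,000 replicates of
3,000-family cohorts for the covariance check; 200 replicates of
10,000-family cohorts for the MR equivalence comparison); each choice is
fixed in the code and recorded in output.

Named scenarios install violations:

- `equal_effects` — the well-behaved baseline (all own-effects equal, no
  indirect effects, continuous measures);
- `zero_female_effect` — female effects and phenotypes identically zero;
- `generational_change` — parental own-effects twice the offspring
  effects (the multiplier is a package choice; any difference breaks the
  across-generation assumption);
- `scale_mismatch` — the maternal measure dichotomized at the median of
  its latent value (emulating a binary smoking indicator combined with a
  continuous index; the threshold default is the package's choice);
- `overlap` — both analysis samples of size \(m = n/(2-f)\) with
  \(f = 0.5\) of each shared, and `rho_resid = 0.3`.

For the overlap split the two samples take families \([0, m)\) and
\([n-m, n)\), sharing \(N_S = 2m-n\); this realizes any overlap fraction
with equal-size regressions.

## Regression engine and closed-form oracles

Per-SNP association is ordinary least squares with an intercept and
homoskedastic SEs — matching the Gaussian simulator; no robust errors, no
covariates beyond conditioning genotypes, no mixed models. Marginal
regressions use the closed-form slope \(S_{xy}/S_{xx}\) vectorized across
SNPs; conditional regressions solve the small normal equations per SNP.
The engine is verified against statsmodels OLS to 10 significant digits
on a small fixture. SNPs with zero residual or predictor variance are
flagged degenerate (beta from the normal equations or 0, SE 0) with a
set-level warning rather than an exception, because a constant phenotype
is a legitimate scenario (no female expresses the trait).

`expected_betas` returns the analytic coefficients: pooled
\(\beta_{CG\_CP}\) is the sex-average of child effects (plus half the
summed indirect effects), parental coefficients are half the parental
own-effects, and with zeroed female phenotypes the pooled child slope is
half the male slope. There is no closed form for a dichotomized maternal
measure (the slope involves the latent density at the threshold); the
function says so and callers fall back to Monte-Carlo. The regression of
a dichotomized measure on dosage is a linear probability model — one
choice among several for a binary trait, recorded in provenance.

## The incoherence demonstration

With female phenotypes identically zero, the role-swapped subtraction
("derive maternal statistics from child and paternal GWAS") targets
\(\beta_{CG\_CP} - \beta_{CG\_FP}\). The package runs the child-phenotype
GWAS in male offspring — the natural design when the phenotype does not
vary at all in females, and the regression engine's sex-stratification
route — giving a derived maternal expectation of \(b - 0.5b = 0.5b \ne 0\)
per SNP while the true maternal coefficient is exactly zero. Fed into
IVW-MR against an offspring outcome caused only by the (male) offspring's
own exposure, the derived statistics produce a strongly significant
"causal effect of maternal exposure" although no mother has the exposure;
the conditional GWAS (offspring outcome on maternal genotype given
offspring genotype) is consistent with zero. Had the child GWAS instead
pooled the sexes, the pooled slope \(0.5b\) would cancel the paternal
\(0.5b\) exactly — the incoherence is that the derived "maternal"
statistics are whatever the child-GWAS design happens to make them,
rather than an estimate of any maternal quantity.

## Mendelian randomization layer

Wald ratio \(\hat\theta = \hat\beta_{Y}/\hat\beta_{X}\) with first-order
SE \(\mathrm{se}_Y/|\hat\beta_X|\) (no second-order exposure-uncertainty
term, no NOME adjustment); multi-SNP estimates are fixed-effect IVW
across Wald ratios. No pleiotropy-robust estimators: the questions here
concern the inputs, not pleiotropy.

In the equivalence demonstration both the exposure *and* outcome paternal
statistics are derived by subtraction from the same cohort's child and
maternal GWAS — as the subtraction workflow prescribes for "partner
outcomes". Both derived sets are then the same affine combination of the
underlying regressions, so the derived-statistics MR is algebraically the
own-phenotype MR with inflated noise: same mean estimate, strictly larger
SE in every matched replicate (~2.9x here). Deriving only the exposure
and regressing an independently measured paternal outcome instead
introduces a visible weak-instrument attenuation (the derived exposure
betas are noisy and their noise no longer cancels), which is itself
an instructive failure mode but not the equivalence statement.

## Numerical choices and limitations

- All estimator arithmetic is double precision with no intermediate
  rounding; the TSV dialect writes 17 significant digits so read∘write
  round-trips are bit-exact (contract: ≥12 significant digits).
- Harmonization follows standard two-sample MR practice: effect/other
  allele match or swap (swap negates beta and complements the
  frequency); palindromic A/T and C/G sites are kept only when both
  frequencies are on the same side of 0.5; irreconcilable or unresolvable
  SNPs are dropped and counted. The dosage convention is the count of
  effect alleles throughout.
- Replicate seeds derive from the master seed via
  `numpy.random.SeedSequence.generate_state`, masked below \(2^{31}\);
  the scheme is recorded in every grid row.
- The simulator emulates independent common SNPs, random mating, Gaussian
  phenotypes and exact effect homogeneity within each stratum. It does
  not emulate LD, assortative mating, population stratification,
  selection, X-linkage, binary disease outcomes, or measurement error in
  reported parental phenotypes. Passing tests therefore show that the
  estimator formulas behave as claimed *under their own stated
  assumptions and violations thereof* — not that real-biobank analyses
  are free of the further complications listed above.
- Monte-Carlo tolerances in the tests are 3 Monte-Carlo SEs for means,
  10% relative for SE-calibration ratios, and 15% relative for the
  overlap-covariance ratio, at the replicate counts stated in each test.
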