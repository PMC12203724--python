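"""Two-sample Mendelian randomization on summary statistics.

Wald ratios and fixed-effect IVW meta-analysis of Wald ratios, with
first-order standard errors (exposure uncertainty ignored, as in common
practice).  Also houses the end-to-end "nonsense estimate" demonstration:
in a population where no female expresses the phenotype, subtraction-
derived maternal statistics feed an MR that confidently reports a causal
effect of the maternal exposure -- whose true effect is exactly zero by
construction -- while the conditional-GWAS route correctly finds nothing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from . import estimators
from .estimators import DeriveMethod, derive_set
from .family_sim import SimParams, scenario, simulate_cohort
from .gwas import RegressionSpec, run_gwas
from .sumstats_io import (
    EmptyIntersectionError,
    SnpAssociation,
    SummaryStatSet,
    ValidationError,
    align_sets,
)

__all__ = [
    "MrMethod",
    "MrResult",
    "wald_ratio",
    "ivw_mr",
    "nonsense_mr_demo",
    "NonsenseDemoReport",
    "equivalence_demo",
    "EquivalenceReport",
]


class MrMethod(str, enum.Enum):
    WALD = "wald"
    IVW_MR = "ivw_mr"


@dataclass(frozen=True)
class MrResult:
    """A causal-effect estimate (outcome units per exposure unit)."""

    estimate: float
    se: float
    method: MrMethod
    n_snps: int

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValidationError(f"MR se must be > 0; got {self.se}")
        if self.n_snps < 1:
            raise ValidationError("MR requires at least one instrument")

    @property
    def z(self) -> float:
        return self.estimate / self.se


def wald_ratio(exposure: SnpAssociation, outcome: SnpAssociation) -> MrResult:
    """Single-SNP MR estimate ``beta_outcome / beta_exposure``.

    First-order delta-method standard error ``se_outcome / |beta_exposure|``.
    The two records must refer to the same SNP with harmonized alleles.
    Scale-invariant: rescaling both betas by a common factor leaves the
    point estimate unchanged (though not the SE).
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValidationError(
            f"exposure ({exposure.snp_id}) and outcome ({outcome.snp_id}) SNPs differ"
        )
    if (exposure.effect_allele, exposure.other_allele) != (
        outcome.effect_allele,
        outcome.other_allele,
    ):
        raise ValidationError(f"{exposure.snp_id}: alleles not harmonized; run align_sets")
    if exposure.beta == 0:
        raise ValidationError(f"{exposure.snp_id}: exposure beta is zero; Wald ratio undefined")
    return MrResult(
        estimate=outcome.beta / exposure.beta,
        se=outcome.se / abs(exposure.beta),
        method=MrMethod.WALD,
        n_snps=1,
    )


def ivw_mr(exposure: SummaryStatSet, outcome: SummaryStatSet) -> MrResult:
    """Fixed-effect inverse-variance meta-analysis of per-SNP Wald ratios.

    Sets are aligned internally (shared SNPs, harmonized alleles); SNPs
    with exactly zero exposure beta or a degenerate outcome SE are
    unusable as instruments and are skipped.  With a single SNP this
    reduces exactly to :func:`wald_ratio`.
    """
    exp_a, out_a = align_sets(exposure, outcome)
    estimates, weights = [], []
    n_used = 0
    for e, o in zip(exp_a.records, out_a.records):
        if e.beta == 0 or not (o.se > 0):
            continue
        ratio = o.beta / e.beta
        w_se = o.se / abs(e.beta)
        estimates.append(ratio)
        weights.append(1.0 / (w_se * w_se))
        n_used += 1
    if n_used == 0:
        raise EmptyIntersectionError("no usable instruments (all exposure betas zero?)")
    est = np.asarray(estimates)
    w = np.asarray(weights)
    return MrResult(
        estimate=float(np.sum(w * est) / np.sum(w)),
        se=float(1.0 / np.sqrt(np.sum(w))),
        method=MrMethod.IVW_MR if n_used > 1 else MrMethod.WALD,
        n_snps=n_used,
    )


@dataclass(frozen=True)
class NonsenseDemoReport:
    """Outcome of the zero-female-phenotype end-to-end demonstration.

    ``subtraction_mr`` is the MR estimate of the "causal effect of the
    maternal exposure" built from subtraction-derived maternal statistics;
    ``conditional_estimate``/``conditional_se`` summarize the conditional-
    GWAS route (offspring outcome on maternal genotype given offspring
    genotype, inverse-variance pooled across SNPs).  ``truth`` is exactly
    0.0: mothers never express the exposure.
    """

    subtraction_mr: MrResult
    conditional_estimate: float
    conditional_se: float
    truth: float
    n_families: int
    n_snps: int
    seed: int

    @property
    def subtraction_z(self) -> float:
        return self.subtraction_mr.z

    @property
    def conditional_z(self) -> float:
        return self.conditional_estimate / self.conditional_se


def _pooled_fixed_effect(stats: SummaryStatSet) -> tuple[float, float]:
    """Inverse-variance pooled coefficient across SNPs (all share one truth)."""
    betas = np.array([r.beta for r in stats.records if r.se > 0])
    ses = np.array([r.se for r in stats.records if r.se > 0])
    w = 1.0 / ses**2
    return float(np.sum(w * betas) / np.sum(w)), float(1.0 / np.sqrt(np.sum(w)))


def nonsense_mr_demo(
    seed: int,
    n_families: int = 50_000,
    n_snps: int = 50,
    effect_size: float = 0.1,
    outcome_theta: float = 0.3,
    male_effects_zero: bool = False,
) -> NonsenseDemoReport:
    """Run the zero-female-exposure scenario end to end.

    Simulates trios in which no female (mother or daughter) expresses the
    exposure, runs the child-exposure GWAS in the stratum where the
    phenotype actually varies (males), the paternal-exposure GWAS, and an
    offspring-outcome GWAS; derives "maternal" statistics by subtraction
    (child minus paternal, the role-swapped subtraction); and feeds them
    into IVW-MR against the offspring outcome.  The derived statistics
    inherit the male/paternal signal, so the MR reports a confident causal
    effect of an exposure no mother has -- while the conditional GWAS
    (offspring outcome on maternal genotype given offspring genotype)
    correctly finds nothing.

    ``male_effects_zero=True`` switches to the global null, under which the
    derived estimate is consistent with zero.
    """
    base = SimParams(
        n_families=n_families,
        n_snps=n_snps,
        seed=seed,
        beta_child_male=0.0 if male_effects_zero else effect_size,
        beta_father_own=0.0 if male_effects_zero else effect_size,
        outcome_theta=outcome_theta,
    )
    params = scenario("zero_female_effect", base)
    cohort = simulate_cohort(params)

    males = np.flatnonzero(cohort.child_sex)
    cp_male = run_gwas(cohort.subset(males), RegressionSpec("child"), trait_label="own_exposure")
    fp = run_gwas(cohort, RegressionSpec("father"), trait_label="paternal_exposure")
    outcome_stats = run_gwas(
        cohort, RegressionSpec("child", outcome=True), trait_label="offspring_outcome"
    )

    import warnings

    with warnings.catch_warnings():
        # The naive pipeline is the procedure under demonstration.
        warnings.simplefilter("ignore", estimators.IndependenceAssumedWarning)
        derived_maternal = derive_set(
            cp_male, fp, DeriveMethod.SUBTRACTION_NAIVE, trait_label="derived_maternal_exposure"
        )
    mr_res = ivw_mr(derived_maternal, outcome_stats)

    conditional = run_gwas(
        cohort,
        RegressionSpec("child", predictor_role="mother", conditioning_roles=("child",), outcome=True),
        trait_label="conditional_maternal",
    )
    cond_est, cond_se = _pooled_fixed_effect(conditional)

    return NonsenseDemoReport(
        subtraction_mr=mr_res,
        conditional_estimate=cond_est,
        conditional_se=cond_se,
        truth=0.0,
        n_families=n_families,
        n_snps=n_snps,
        seed=seed,
    )


@dataclass(frozen=True)
class EquivalenceReport:
    """Matched-replicate comparison of own-phenotype MR vs derived-stats MR.

    Both routes target the same causal effect ``theta`` of the exposure on
    the outcome; the derived route (subtraction paternal statistics against
    the paternal outcome) is the less powerful way of estimating it.
    """

    theta: float
    mean_own: float
    mean_derived: float
    sd_own: float
    sd_derived: float
    mean_se_own: float
    mean_se_derived: float
    frac_derived_se_larger: float
    n_replicates: int

    @property
    def mc_se_own(self) -> float:
        return self.sd_own / np.sqrt(self.n_replicates)

    @property
    def mc_se_derived(self) -> float:
        return self.sd_derived / np.sqrt(self.n_replicates)


def equivalence_demo(
    seed: int,
    n_replicates: int = 200,
    n_families: int = 10_000,
    n_snps: int = 50,
    effect_size: float = 0.1,
    theta: float = 0.2,
) -> EquivalenceReport:
    """Monte-Carlo demonstration that derived-stats MR re-estimates own MR.

    Under equal effects across sexes and generations, MR of the paternal
    exposure on the paternal outcome -- with *both* exposure and outcome
    statistics derived by subtraction (child GWAS minus maternal GWAS),
    as the subtraction workflow prescribes -- estimates the same ``theta``
    as MR of the own exposure on the own outcome.  Because both derived
    sets are the same affine combination of the underlying regressions,
    the analysis is the own-phenotype MR in disguise, only with inflated
    standard errors, replicate by replicate.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates).astype(np.int64) & 0x7FFFFFFF
    own, derived, se_own, se_derived = [], [], [], []
    for s in seeds:
        base = SimParams(
            n_families=n_families,
            n_snps=n_snps,
            seed=int(s),
            beta_child_male=effect_size,
            outcome_theta=theta,
        )
        params = scenario("equal_effects", base)
        cohort = simulate_cohort(params)
        cp = run_gwas(cohort, RegressionSpec("child"))
        mp = run_gwas(cohort, RegressionSpec("mother"))
        own_outcome = run_gwas(cohort, RegressionSpec("child", outcome=True))
        mother_outcome = run_gwas(cohort, RegressionSpec("mother", outcome=True))

        res_own = ivw_mr(cp, own_outcome)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", estimators.IndependenceAssumedWarning)
            derived_fp = derive_set(cp, mp, DeriveMethod.SUBTRACTION_NAIVE)
            derived_fp_outcome = derive_set(
                own_outcome, mother_outcome, DeriveMethod.SUBTRACTION_NAIVE
            )
        res_derived = ivw_mr(derived_fp, derived_fp_outcome)
        own.append(res_own.estimate)
        derived.append(res_derived.estimate)
        se_own.append(res_own.se)
        se_derived.append(res_derived.se)

    own = np.asarray(own)
    derived = np.asarray(derived)
    se_own = np.asarray(se_own)
    se_derived = np.asarray(se_derived)
    return EquivalenceReport(
        theta=theta,
        mean_own=float(own.mean()),
        mean_derived=float(derived.mean()),
        sd_own=float(own.std(ddof=1)),
        sd_derived=float(derived.std(ddof=1)),
        mean_se_own=float(se_own.mean()),
        mean_se_derived=float(se_derived.mean()),
        frac_derived_se_larger=float((se_derived > se_own).mean()),
        n_replicates=n_replicates,
    )
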