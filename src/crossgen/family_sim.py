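"""Family-trio simulator: the generative oracle behind every estimator claim.

Trios are simulated under a fully specified model: parental genotypes in
Hardy-Weinberg equilibrium at known allele frequencies, random mating,
Mendelian transmission of one allele per parent, and additive phenotypes

``P = sum_j beta_j * G_j  (+ indirect parental terms for children)  + e``

with unit-variance Gaussian residuals; the mother's and child's residuals
may be correlated (``rho_resid``), which is what makes the two regressions'
coefficient estimates covary under sample overlap.  Assortative mating,
population stratification and LD are deliberately absent -- they are
assumptions of the estimators under study, kept true by construction --
while the assumptions the critique targets (equal effects across sexes and
generations, same measurement scale) are switchable violations exposed as
named scenarios.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .sumstats_io import ValidationError

__all__ = [
    "MaternalMeasure",
    "SimParams",
    "FamilyCohort",
    "simulate_cohort",
    "scenario",
    "SCENARIOS",
    "overlap_indices",
    "mendelian_consistency",
    "analytic_mother_child_correlation",
]


class MaternalMeasure(str, enum.Enum):
    CONTINUOUS = "continuous"
    DICHOTOMIZED = "dichotomized"


def _as_snp_vector(value: float | Sequence[float], n_snps: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_snps, float(arr))
    if arr.shape != (n_snps,):
        raise ValidationError(f"{name} must be scalar or length n_snps={n_snps}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class SimParams:
    """Parameter block for one simulated trio cohort.

    All genetic effects are in phenotype-SD units per effect-allele count
    (residual variance is 1 by construction) and may be scalars (shared by
    all SNPs) or per-SNP vectors.

    Parameters
    ----------
    n_families, n_snps
        Cohort dimensions; SNPs are independent (no LD).
    maf
        Effect-allele frequency per SNP, in (0.01, 0.5).
    beta_child_male, beta_child_female
        Direct effect of own genotype on own phenotype in the offspring
        generation, per sex.
    beta_mother_own, beta_father_own
        Direct own-genotype effects in the parental generation; setting
        these different from the child effects violates the
        across-generation homogeneity both estimators assume.
    delta_maternal, delta_paternal
        Indirect (dynastic) effect of a parent's genotype on the child's
        phenotype, mediated by the parental phenotype/environment.
    rho_resid
        Residual mother-child phenotype correlation in (-1, 1), realized
        through a jointly Gaussian residual pair.
    overlap_fraction
        Fraction of each regression's sample shared with the other
        regression when the cohort is split for two-sample analyses
        (see :func:`overlap_indices`).
    maternal_measure
        ``continuous`` or ``dichotomized``; dichotomization thresholds the
        latent maternal phenotype (at its median unless
        ``dichotomize_threshold`` is given), emulating a binary
        smoking/non-smoking measure combined with a continuous index.
    outcome_theta
        When not None, each person also gets an outcome phenotype
        ``Y = outcome_theta * P + e_Y`` with independent unit Gaussian
        noise -- the causal system for Mendelian-randomization checks.
    female_phenotype_zero
        Force the exposure phenotype of all females (mothers and female
        children) to exactly zero: a population in which no females
        express the phenotype at all.
    seed
        Mandatory; identical params (including seed) give a bit-identical
        cohort.
    """

    n_families: int
    n_snps: int
    seed: int
    maf: float | Sequence[float] = 0.3
    beta_child_male: float | Sequence[float] = 0.1
    beta_child_female: float | Sequence[float] = 0.1
    beta_mother_own: float | Sequence[float] = 0.1
    beta_father_own: float | Sequence[float] = 0.1
    delta_maternal: float | Sequence[float] = 0.0
    delta_paternal: float | Sequence[float] = 0.0
    rho_resid: float = 0.0
    overlap_fraction: float = 0.0
    maternal_measure: MaternalMeasure | str = MaternalMeasure.CONTINUOUS
    dichotomize_threshold: float | None = None
    outcome_theta: float | None = None
    female_phenotype_zero: bool = False

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_snps < 1:
            raise ValidationError("n_families and n_snps must be positive")
        if self.seed is None or int(self.seed) != self.seed:
            raise ValidationError("seed is mandatory and must be an integer")
        maf = self.maf_vector()
        if np.any((maf <= 0.01) | (maf >= 0.5)):
            raise ValidationError("maf must lie in (0.01, 0.5) per SNP")
        if not (-1 < self.rho_resid < 1):
            raise ValidationError("rho_resid must lie in (-1, 1)")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValidationError("overlap_fraction must lie in [0, 1]")
        MaternalMeasure(self.maternal_measure)  # raises on unknown value
        for name in (
            "beta_child_male",
            "beta_child_female",
            "beta_mother_own",
            "beta_father_own",
            "delta_maternal",
            "delta_paternal",
        ):
            self.effect_vector(name)  # validates shape/finiteness

    def maf_vector(self) -> np.ndarray:
        return _as_snp_vector(self.maf, self.n_snps, "maf")

    def effect_vector(self, name: str) -> np.ndarray:
        return _as_snp_vector(getattr(self, name), self.n_snps, name)

    def genotype_variances(self) -> np.ndarray:
        """Per-SNP dosage variance 2*p*(1-p) under Hardy-Weinberg."""
        p = self.maf_vector()
        return 2.0 * p * (1.0 - p)


@dataclass
class FamilyCohort:
    """Simulated trio genotypes, sexes and phenotypes.

    Genotype matrices hold 0/1/2 effect-allele counts, one row per family,
    one column per SNP.  ``child_sex`` is True for male offspring.
    """

    mother_geno: np.ndarray
    father_geno: np.ndarray
    child_geno: np.ndarray
    child_sex: np.ndarray
    mother_pheno: np.ndarray
    father_pheno: np.ndarray
    child_pheno: np.ndarray
    params: SimParams
    mother_latent: np.ndarray | None = None
    mother_outcome: np.ndarray | None = None
    father_outcome: np.ndarray | None = None
    child_outcome: np.ndarray | None = None

    @property
    def n_families(self) -> int:
        return self.child_geno.shape[0]

    @property
    def n_snps(self) -> int:
        return self.child_geno.shape[1]

    def genotypes(self, role: str) -> np.ndarray:
        return {"mother": self.mother_geno, "father": self.father_geno, "child": self.child_geno}[
            role
        ]

    def phenotypes(self, role: str, outcome: bool = False) -> np.ndarray:
        if outcome:
            arr = {
                "mother": self.mother_outcome,
                "father": self.father_outcome,
                "child": self.child_outcome,
            }[role]
            if arr is None:
                raise ValidationError("cohort was simulated without an outcome model")
            return arr
        return {
            "mother": self.mother_pheno,
            "father": self.father_pheno,
            "child": self.child_pheno,
        }[role]

    def subset(self, index: np.ndarray) -> "FamilyCohort":
        """Cohort restricted to the given family indices (copies views)."""
        pick = lambda a: None if a is None else a[index]
        return FamilyCohort(
            mother_geno=self.mother_geno[index],
            father_geno=self.father_geno[index],
            child_geno=self.child_geno[index],
            child_sex=self.child_sex[index],
            mother_pheno=self.mother_pheno[index],
            father_pheno=self.father_pheno[index],
            child_pheno=self.child_pheno[index],
            params=self.params,
            mother_latent=pick(self.mother_latent),
            mother_outcome=pick(self.mother_outcome),
            father_outcome=pick(self.father_outcome),
            child_outcome=pick(self.child_outcome),
        )


def simulate_cohort(params: SimParams) -> FamilyCohort:
    """Draw one trio cohort under ``params``.

    Parents are drawn in Hardy-Weinberg equilibrium at the given allele
    frequencies; mating is random; each parent transmits one of their two
    alleles to the child uniformly at random.  Exposure phenotypes are
    additive in dosage with sex/generation-appropriate effects plus
    (for children) the parental indirect terms, plus Gaussian residuals
    with the requested mother-child residual correlation.  Dichotomization
    of the maternal measure, zeroing of female phenotypes, and the optional
    outcome phenotype are applied last, in that order.
    """
    rng = np.random.default_rng(params.seed)
    n, m = params.n_families, params.n_snps
    p = params.maf_vector()

    # Parent dosage = sum of two independent Bernoulli(p) alleles (HWE).
    mother_geno = (
        (rng.random((n, m)) < p).astype(np.int8) + (rng.random((n, m)) < p).astype(np.int8)
    )
    father_geno = (
        (rng.random((n, m)) < p).astype(np.int8) + (rng.random((n, m)) < p).astype(np.int8)
    )
    # Mendelian transmission: a parent with dosage d passes the effect
    # allele with probability d/2 (certain for homozygotes, fair coin for
    # heterozygotes).
    from_mother = (rng.random((n, m)) * 2.0 < mother_geno).astype(np.int8)
    from_father = (rng.random((n, m)) * 2.0 < father_geno).astype(np.int8)
    child_geno = from_mother + from_father

    child_sex = rng.random(n) < 0.5  # True = male

    rho = params.rho_resid
    z = rng.standard_normal((n, 2))
    e_mother = z[:, 0]
    e_child = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    e_father = rng.standard_normal(n)

    b_mother = params.effect_vector("beta_mother_own")
    b_father = params.effect_vector("beta_father_own")
    b_male = params.effect_vector("beta_child_male")
    b_female = params.effect_vector("beta_child_female")
    d_mat = params.effect_vector("delta_maternal")
    d_pat = params.effect_vector("delta_paternal")

    mother_latent = mother_geno @ b_mother + e_mother
    father_pheno = father_geno @ b_father + e_father
    b_child = np.where(child_sex[:, None], b_male[None, :], b_female[None, :])
    child_pheno = (
        (child_geno * b_child).sum(axis=1)
        + mother_geno @ d_mat
        + father_geno @ d_pat
        + e_child
    )

    mother_pheno = mother_latent.copy()
    if MaternalMeasure(params.maternal_measure) is MaternalMeasure.DICHOTOMIZED:
        thr = params.dichotomize_threshold
        if thr is None:
            thr = float(np.median(mother_latent))
        mother_pheno = (mother_latent > thr).astype(float)

    if params.female_phenotype_zero:
        mother_pheno = np.zeros(n)
        child_pheno = np.where(child_sex, child_pheno, 0.0)

    mother_outcome = father_outcome = child_outcome = None
    if params.outcome_theta is not None:
        th = float(params.outcome_theta)
        mother_outcome = th * mother_pheno + rng.standard_normal(n)
        father_outcome = th * father_pheno + rng.standard_normal(n)
        child_outcome = th * child_pheno + rng.standard_normal(n)

    return FamilyCohort(
        mother_geno=mother_geno,
        father_geno=father_geno,
        child_geno=child_geno,
        child_sex=child_sex,
        mother_pheno=mother_pheno,
        father_pheno=father_pheno,
        child_pheno=child_pheno,
        params=params,
        mother_latent=mother_latent,
        mother_outcome=mother_outcome,
        father_outcome=father_outcome,
        child_outcome=child_outcome,
    )


_GENERATIONAL_MULTIPLE = 2.0


def _scenario_equal_effects(base: SimParams) -> SimParams:
    b = base.beta_child_male
    return replace(
        base,
        beta_child_female=b,
        beta_mother_own=b,
        beta_father_own=b,
        delta_maternal=0.0,
        delta_paternal=0.0,
        maternal_measure=MaternalMeasure.CONTINUOUS,
        female_phenotype_zero=False,
    )


def _scenario_zero_female_effect(base: SimParams) -> SimParams:
    return replace(
        _scenario_equal_effects(base),
        beta_child_female=0.0,
        beta_mother_own=0.0,
        female_phenotype_zero=True,
    )


def _scenario_generational_change(base: SimParams) -> SimParams:
    b = np.asarray(base.beta_child_male, dtype=float)
    parental = b * _GENERATIONAL_MULTIPLE
    parental = float(parental) if parental.ndim == 0 else parental
    return replace(
        _scenario_equal_effects(base), beta_mother_own=parental, beta_father_own=parental
    )


def _scenario_scale_mismatch(base: SimParams) -> SimParams:
    return replace(
        _scenario_equal_effects(base),
        maternal_measure=MaternalMeasure.DICHOTOMIZED,
        dichotomize_threshold=None,  # median split of the latent measure
    )


def _scenario_overlap(base: SimParams) -> SimParams:
    return replace(_scenario_equal_effects(base), overlap_fraction=0.5, rho_resid=0.3)


SCENARIOS = {
    "equal_effects": _scenario_equal_effects,
    "zero_female_effect": _scenario_zero_female_effect,
    "generational_change": _scenario_generational_change,
    "scale_mismatch": _scenario_scale_mismatch,
    "overlap": _scenario_overlap,
}


def scenario(name: str, base: SimParams) -> SimParams:
    """Install a named assumption-violation (or the well-behaved baseline).

    ``equal_effects``      -- all own-genotype effects equal across sexes and
                              generations; both estimators unbiased.
    ``zero_female_effect`` -- no female expresses the phenotype (effects and
                              phenotype zero); the incoherence scenario.
    ``generational_change``-- parental own-effects are twice the offspring
                              effects; subtraction becomes badly biased.
    ``scale_mismatch``     -- maternal measure dichotomized at its median;
                              the two regressions are on different scales.
    ``overlap``            -- half-overlapping samples with residual
                              mother-child correlation 0.3; coefficient
                              estimates covary.
    """
    try:
        fn = SCENARIOS[name]
    except KeyError:
        raise ValidationError(
            f"unknown scenario {name!r}; valid scenarios: {sorted(SCENARIOS)}"
        ) from None
    return fn(base)


def overlap_indices(n_families: int, overlap_fraction: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Split a cohort into two equal-size analysis samples with given overlap.

    Both samples have size ``m = round(n / (2 - f))``; the first takes
    families ``[0, m)`` and the second ``[n - m, n)``, sharing
    ``N_S = 2m - n`` families so that ``N_S / m = f`` (up to rounding).
    Returns ``(index_a, index_b, n_shared)``.
    """
    f = overlap_fraction
    if not (0 <= f <= 1):
        raise ValidationError("overlap_fraction must lie in [0, 1]")
    m = int(round(n_families / (2.0 - f)))
    m = max(m, (n_families + 1) // 2)
    n_shared = 2 * m - n_families
    return np.arange(0, m), np.arange(n_families - m, n_families), n_shared


def mendelian_consistency(cohort: FamilyCohort) -> float:
    """Fraction of family-SNP pairs whose child dosage is attainable.

    A child dosage c is attainable iff ``(#homozygous-alt parents) <= c <=
    (#parents carrying the allele)``; the simulator should achieve 1.0
    exactly.
    """
    lo = (cohort.mother_geno == 2).astype(np.int8) + (cohort.father_geno == 2).astype(np.int8)
    hi = (cohort.mother_geno >= 1).astype(np.int8) + (cohort.father_geno >= 1).astype(np.int8)
    ok = (cohort.child_geno >= lo) & (cohort.child_geno <= hi)
    return float(ok.mean())


def analytic_mother_child_correlation(params: SimParams) -> float:
    """Population correlation between maternal and child exposure phenotypes.

    Closed form for continuous measures: the genetic covariance runs
    through the transmitted half of the maternal genotype (plus any
    maternal indirect term), and the residual covariance is ``rho_resid``.
    Unavailable (raises) for dichotomized or zeroed-female measures.
    """
    if MaternalMeasure(params.maternal_measure) is not MaternalMeasure.CONTINUOUS:
        raise ValidationError("no closed form for a dichotomized maternal measure")
    if params.female_phenotype_zero:
        raise ValidationError("no closed form when female phenotypes are forced to zero")
    v_g = params.genotype_variances()
    mu_g = 2.0 * params.maf_vector()
    b_m = params.effect_vector("beta_mother_own")
    b_male = params.effect_vector("beta_child_male")
    b_female = params.effect_vector("beta_child_female")
    b_bar = 0.5 * (b_male + b_female)
    d_mat = params.effect_vector("delta_maternal")
    d_pat = params.effect_vector("delta_paternal")

    cov_cm = float(np.sum(0.5 * b_bar * b_m * v_g + d_mat * b_m * v_g)) + params.rho_resid
    var_m = float(np.sum(b_m**2 * v_g)) + 1.0
    # Child variance: within-sex genetic variance, between-sex mean shift,
    # indirect terms and their covariance with the transmitted genotype.
    mean_male = float(np.sum(b_male * mu_g))
    mean_female = float(np.sum(b_female * mu_g))
    var_c = (
        float(np.sum(0.5 * (b_male**2 + b_female**2) * v_g))
        + 0.25 * (mean_male - mean_female) ** 2
        + float(np.sum((d_mat**2 + d_pat**2) * v_g))
        + float(np.sum(2.0 * b_bar * (d_mat + d_pat) * 0.5 * v_g))
        + 1.0
    )
    return cov_cm / np.sqrt(var_m * var_c)
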