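"""Per-SNP regression engines and their closed-form expectations.

Three marginal regressions define the quantities of interest -- child,
maternal, or paternal phenotype regressed on *child* genotype dosage --
and a conditional regression (offspring outcome on a parental genotype
with the offspring's own genotype as covariate) isolates the parental
indirect effect.  All regressions are ordinary least squares with an
intercept and homoskedastic standard errors, matching the Gaussian
simulator.  ``expected_betas`` provides the analytic counterparts used
as oracles: under random mating each parent transmits half their
genotype, so ``cov(G_child, G_parent) = var(G)/2`` and a parental
own-effect ``b`` shows up in the child-genotype regression as ``b/2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .family_sim import FamilyCohort, MaternalMeasure, SimParams
from .sumstats_io import Role, SnpAssociation, SummaryStatSet, ValidationError

__all__ = [
    "RegressionSpec",
    "run_gwas",
    "expected_betas",
    "ExpectedBetas",
    "NoClosedFormError",
    "DegenerateRegressionWarning",
]


class NoClosedFormError(ValidationError):
    """The requested analytic expectation has no closed form."""


class DegenerateRegressionWarning(UserWarning):
    """At least one per-SNP regression had zero residual or predictor variance."""


_ROLE_FOR_RESPONSE = {
    "child": Role.CHILD_PHENO_CHILD_GENO,
    "mother": Role.MATERNAL_PHENO_CHILD_GENO,
    "father": Role.PATERNAL_PHENO_CHILD_GENO,
}


@dataclass(frozen=True)
class RegressionSpec:
    """Which phenotype is regressed on whose genotype, conditioning on whom.

    ``response_role`` picks the phenotype (``child``, ``mother``,
    ``father``); ``predictor_role`` picks the genotype whose per-SNP
    coefficient is reported; ``conditioning_roles`` lists further roles
    whose genotype at the same SNP enters as a covariate.  ``outcome=True``
    uses the role's outcome phenotype instead of the exposure.
    """

    response_role: str
    predictor_role: str = "child"
    conditioning_roles: tuple[str, ...] = ()
    outcome: bool = False

    def __post_init__(self) -> None:
        valid = {"child", "mother", "father"}
        for r in (self.response_role, self.predictor_role, *self.conditioning_roles):
            if r not in valid:
                raise ValidationError(f"unknown role {r!r}; valid roles: {sorted(valid)}")
        if self.predictor_role in self.conditioning_roles:
            raise ValidationError("conditioning_roles must not include predictor_role")


def _marginal_ols(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized simple OLS of y on each genotype column (with intercept)."""
    n = y.shape[0]
    gc = G - G.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    sxx = (gc * gc).sum(axis=0)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    rss = np.maximum(syy - beta * sxy, 0.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(sxx > 0, rss / dof / np.where(sxx > 0, sxx, 1.0), 0.0))
    degenerate = (sxx <= 0) | (rss <= 0)
    return beta, se, degenerate


def _conditional_ols(
    y: np.ndarray, G_pred: np.ndarray, G_cond: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP OLS with intercept, predictor dosage and conditioning dosages."""
    n, m = G_pred.shape
    k = 2 + len(G_cond)
    beta = np.zeros(m)
    se = np.zeros(m)
    degenerate = np.zeros(m, dtype=bool)
    dof = n - k
    for j in range(m):
        X = np.empty((n, k))
        X[:, 0] = 1.0
        X[:, 1] = G_pred[:, j]
        for i, g in enumerate(G_cond):
            X[:, 2 + i] = g[:, j]
        xtx = X.T @ X
        xty = X.T @ y
        try:
            coef = np.linalg.solve(xtx, xty)
            inv11 = np.linalg.inv(xtx)[1, 1]
        except np.linalg.LinAlgError:
            degenerate[j] = True
            continue
        rss = float(y @ y - coef @ xty)
        if rss <= 0 or inv11 <= 0:
            degenerate[j] = True
            beta[j] = coef[1]
            continue
        beta[j] = coef[1]
        se[j] = np.sqrt(rss / dof * inv11)
    return beta, se, degenerate


def run_gwas(
    cohort: FamilyCohort,
    spec: RegressionSpec,
    trait_label: str | None = None,
) -> SummaryStatSet:
    """Run the per-SNP regressions of ``spec`` over a cohort.

    Returns one :class:`SnpAssociation` per SNP with the OLS coefficient
    of the predictor dosage, its homoskedastic standard error, the sample
    size, and the effect-allele frequency observed in the predictor-role
    sample.  SNPs with zero residual variance (e.g. a constant phenotype)
    or zero predictor variance get ``beta`` from the normal equations
    (zero when undefined), ``se = 0`` flagged degenerate, and a set-level
    warning is emitted.

    To stratify (e.g. a male-only child GWAS) subset the cohort first:
    ``run_gwas(cohort.subset(cohort.child_sex), spec)``.
    """
    y = np.asarray(cohort.phenotypes(spec.response_role, outcome=spec.outcome), dtype=float)
    G = cohort.genotypes(spec.predictor_role).astype(float)
    n = y.shape[0]
    if n < len(spec.conditioning_roles) + 3:
        raise ValidationError("too few families for the requested regression")
    if spec.conditioning_roles:
        G_cond = [cohort.genotypes(r).astype(float) for r in spec.conditioning_roles]
        beta, se, degenerate = _conditional_ols(y, G, G_cond)
    else:
        beta, se, degenerate = _marginal_ols(y, G)

    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} of {G.shape[1]} per-SNP regressions were "
            "degenerate (zero residual or predictor variance)",
            DegenerateRegressionWarning,
            stacklevel=2,
        )

    eaf = G.mean(axis=0) / 2.0
    records = [
        SnpAssociation(
            snp_id=f"snp{j + 1:05d}",
            effect_allele="A",
            other_allele="G",
            eaf=float(eaf[j]) if 0.0 < eaf[j] < 1.0 else None,
            beta=float(beta[j]),
            se=float(se[j]),
            n=n,
            degenerate=bool(degenerate[j]),
        )
        for j in range(G.shape[1])
    ]
    if spec.conditioning_roles or spec.predictor_role != "child":
        role = Role.DERIVED
        provenance = (
            f"conditional GWAS: {spec.response_role} "
            f"{'outcome' if spec.outcome else 'phenotype'} on {spec.predictor_role} genotype"
            + (f" | {','.join(spec.conditioning_roles)} genotype" if spec.conditioning_roles else "")
        )
    else:
        role = _ROLE_FOR_RESPONSE[spec.response_role]
        provenance = (
            f"OLS GWAS: {spec.response_role} "
            f"{'outcome' if spec.outcome else 'phenotype'} on child genotype"
        )
    return SummaryStatSet(
        role=role,
        trait_label=trait_label or f"{spec.response_role}_{'outcome' if spec.outcome else 'pheno'}",
        records=records,
        provenance=provenance,
    )


@dataclass(frozen=True)
class ExpectedBetas:
    """Analytic per-SNP population regression coefficients for a parameter set.

    ``beta_cg_cp`` pools the sexes (the coefficient a mixed-sex child GWAS
    estimates); ``beta_cg_cp_male`` / ``_female`` are the sex strata.
    ``subtraction_paternal`` is the expectation of the child-minus-maternal
    subtraction estimator, and ``subtraction_maternal`` its role-swapped
    analogue (child minus paternal); ``subtraction_maternal_male_cp`` uses
    the male-stratum child coefficient, the natural child GWAS when the
    phenotype does not vary in females.
    """

    beta_cg_cp: np.ndarray
    beta_cg_cp_male: np.ndarray
    beta_cg_cp_female: np.ndarray
    beta_cg_mp: np.ndarray
    beta_cg_fp: np.ndarray
    subtraction_paternal: np.ndarray
    subtraction_maternal: np.ndarray
    subtraction_maternal_male_cp: np.ndarray


def expected_betas(params: SimParams) -> ExpectedBetas:
    """Closed-form population regression coefficients under ``params``.

    Exact for continuous measures: with random mating and Mendelian
    transmission, ``cov(G_child, G_parent) = var(G)/2``, so a parental
    own-effect ``b`` contributes ``b/2`` to the regression of that
    parent's phenotype on child genotype, and a parental indirect effect
    ``d`` contributes ``d/2`` to the child-phenotype regression.  Zeroed
    female phenotypes simply zero the corresponding terms.  There is no
    closed form for a dichotomized maternal measure; Monte-Carlo
    (``run_gwas`` on simulated cohorts) is the fallback there.
    """
    if MaternalMeasure(params.maternal_measure) is not MaternalMeasure.CONTINUOUS:
        raise NoClosedFormError(
            "no closed form for a dichotomized maternal measure; use Monte-Carlo "
            "via simulate_cohort + run_gwas"
        )
    b_male = params.effect_vector("beta_child_male")
    b_female = params.effect_vector("beta_child_female")
    b_mother = params.effect_vector("beta_mother_own")
    b_father = params.effect_vector("beta_father_own")
    d_mat = params.effect_vector("delta_maternal")
    d_pat = params.effect_vector("delta_paternal")

    if params.female_phenotype_zero:
        b_female = np.zeros_like(b_female)
        b_mother_eff = np.zeros_like(b_mother)
        d_eff = np.zeros_like(d_mat)  # female children contribute nothing
        cp_male = b_male + 0.5 * (d_mat + d_pat)
        cp_female = np.zeros_like(b_male)
        cp_pooled = 0.5 * cp_male
        mp = np.zeros_like(b_mother)
    else:
        indirect = 0.5 * (d_mat + d_pat)
        cp_male = b_male + indirect
        cp_female = b_female + indirect
        cp_pooled = 0.5 * (cp_male + cp_female)
        mp = 0.5 * b_mother
    fp = 0.5 * b_father

    return ExpectedBetas(
        beta_cg_cp=cp_pooled,
        beta_cg_cp_male=cp_male,
        beta_cg_cp_female=cp_female,
        beta_cg_mp=mp,
        beta_cg_fp=fp,
        subtraction_paternal=cp_pooled - mp,
        subtraction_maternal=cp_pooled - fp,
        subtraction_maternal_male_cp=cp_male - fp,
    )
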