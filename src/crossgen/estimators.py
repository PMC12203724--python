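"""Per-SNP estimators for cross-generational GWAS summary statistics.

Setting: with genotype dosages measured on the child, three population
regression coefficients are in play for a phenotype such as smoking --
child phenotype on child genotype (``beta_cp``), maternal phenotype on
child genotype (``beta_mp``), and paternal phenotype on child genotype
(``beta_fp``).  Under random mating, no indirect effects, and genetic
effects equal across sexes and generations, ``beta_fp = beta_mp =
0.5 * beta_cp``, which motivates two ways to manufacture paternal
statistics from the other two regressions:

* the **subtraction** estimator ``beta_fp_hat = beta_cp_hat - beta_mp_hat``
  with naive standard error ``sqrt(var_cp + var_mp)``, correct only when
  the two regressions are independent;
* the **inverse-variance-weighted (IVW)** combination of ``0.5*beta_cp_hat``
  (weight ``w1 = 4/var_cp``) and ``beta_mp_hat`` (weight ``w2 = 1/var_mp``),
  the minimum-variance linear combination of the two.

When the two regressions share samples and the maternal and child
phenotypes are residually correlated, their coefficient estimates covary;
the covariance is a single genome-wide intercept (the bivariate-LDSC-style
quantity ``N_S / sqrt(N_cp * N_mp) * rho``) times the per-SNP product of
standard errors, and feeds the corrected subtraction standard error
``sqrt(var_cp + var_mp - 2*cov)``.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

from .sumstats_io import (
    Role,
    SnpAssociation,
    SummaryStatSet,
    ValidationError,
)

__all__ = [
    "OverlapModel",
    "DerivedEstimate",
    "IvwWeights",
    "DeriveMethod",
    "subtraction_estimate",
    "subtraction_se_naive",
    "subtraction_se_corrected",
    "covariance_from_overlap",
    "ivw_weights",
    "ivw_estimate",
    "ivw_se",
    "derive_set",
    "IndependenceAssumedWarning",
]


class IndependenceAssumedWarning(UserWarning):
    """No overlap model supplied: naive SEs are only correct under independence."""


class DeriveMethod(str, enum.Enum):
    SUBTRACTION_NAIVE = "subtraction_naive"
    SUBTRACTION_CORRECTED = "subtraction_corrected"
    IVW = "ivw"


@dataclass(frozen=True)
class OverlapModel:
    """Sample-overlap and phenotype-correlation parameters.

    Governs the covariance between the child-phenotype and maternal-
    phenotype regression coefficient estimates.  ``intercept`` may be
    supplied directly (e.g. from bivariate LD score regression); when
    absent it is computed as ``n_overlap / sqrt(n_cp * n_mp) *
    pheno_correlation``.

    Parameters
    ----------
    n_cp, n_mp
        Sample sizes of the child-phenotype and maternal-phenotype
        regressions.
    n_overlap
        Effective number of individuals contributing to both regressions
        (``N_S``); treated as a user-supplied scalar.
    pheno_correlation
        Correlation ``rho`` between maternal and child phenotypes.
    """

    n_cp: int
    n_mp: int
    n_overlap: float = 0.0
    pheno_correlation: float = 0.0
    intercept: float | None = None

    def __post_init__(self) -> None:
        if self.n_cp < 1 or self.n_mp < 1:
            raise ValidationError("sample sizes must be positive")
        if not (0 <= self.n_overlap <= min(self.n_cp, self.n_mp)):
            raise ValidationError(
                f"n_overlap must lie in [0, min(n_cp, n_mp)]; got {self.n_overlap}"
            )
        if abs(self.pheno_correlation) > 1:
            raise ValidationError("pheno_correlation must lie in [-1, 1]")
        if self.intercept is not None:
            implied = self._implied_intercept()
            if (self.n_overlap != 0 or self.pheno_correlation != 0) and abs(
                self.intercept - implied
            ) > 1e-9:
                raise ValidationError(
                    f"supplied intercept {self.intercept} disagrees with "
                    f"n_overlap/sqrt(n_cp*n_mp)*rho = {implied}"
                )

    def _implied_intercept(self) -> float:
        return self.n_overlap / math.sqrt(self.n_cp * self.n_mp) * self.pheno_correlation

    @property
    def effective_intercept(self) -> float:
        """The intercept actually used: supplied, else implied by overlap."""
        if self.intercept is not None:
            return self.intercept
        return self._implied_intercept()


@dataclass(frozen=True)
class IvwWeights:
    """The two IVW weights: ``w1 = 4/var_cp`` and ``w2 = 1/var_mp``."""

    w1: float
    w2: float

    def __post_init__(self) -> None:
        if not (self.w1 > 0 and self.w2 > 0):
            raise ValidationError("IVW weights must be strictly positive")


@dataclass(frozen=True)
class DerivedEstimate:
    """A combined per-SNP estimate with its provenance.

    ``components`` records the (beta, variance) pairs and the covariance
    that entered the combination, so a derived set can be audited.
    """

    beta_hat: float
    se_hat: float
    method: DeriveMethod
    components: tuple[tuple[float, float], tuple[float, float], float]

    def __post_init__(self) -> None:
        if not (self.se_hat > 0):
            raise ValidationError(f"derived se must be > 0; got {self.se_hat}")


def _require_finite(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not math.isfinite(v):
            raise ValidationError(f"{name} must be finite; got {v}")


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not (v > 0 and math.isfinite(v)):
            raise ValidationError(f"{name} must be finite and > 0; got {v}")


def subtraction_estimate(beta_cp: float, beta_mp: float) -> float:
    """Subtraction estimator of the paternal coefficient: ``beta_cp - beta_mp``.

    Role-symmetric: passing (child, paternal) coefficients derives the
    maternal coefficient through the identical code path.
    """
    _require_finite(beta_cp=beta_cp, beta_mp=beta_mp)
    return beta_cp - beta_mp


def subtraction_se_naive(var_cp: float, var_mp: float) -> float:
    """Naive subtraction SE ``sqrt(var_cp + var_mp)``.

    Correct only when the two coefficient estimates are independent
    (disjoint samples, or no residual mother-child phenotype correlation).
    """
    _require_positive(var_cp=var_cp, var_mp=var_mp)
    return math.sqrt(var_cp + var_mp)


def subtraction_se_corrected(var_cp: float, var_mp: float, cov: float) -> float:
    """Subtraction SE allowing for coefficient covariance.

    ``sqrt(var_cp + var_mp - 2*cov)``; strictly smaller than the naive SE
    whenever ``cov > 0`` (positive residual mother-child correlation under
    sample overlap), which is why the naive SE is conservative in
    real-world applications.
    """
    _require_positive(var_cp=var_cp, var_mp=var_mp)
    _require_finite(cov=cov)
    radicand = var_cp + var_mp - 2.0 * cov
    if not (radicand > 0):
        raise ValidationError(
            f"var_cp + var_mp - 2*cov must be > 0; cov={cov} gives radicand {radicand}"
        )
    return math.sqrt(radicand)


def covariance_from_overlap(model: OverlapModel, se_cp: float, se_mp: float) -> float:
    """Per-SNP coefficient covariance from the overlap intercept.

    ``cov = int * se_cp * se_mp`` where ``int = N_S/sqrt(N_cp*N_mp) * rho``
    unless an intercept was supplied directly.  Zero overlap or zero
    phenotype correlation gives exactly zero.  The intercept is a single
    genome-wide scalar; only the SE product varies per SNP.
    """
    _require_positive(se_cp=se_cp, se_mp=se_mp)
    return model.effective_intercept * se_cp * se_mp


def ivw_weights(var_cp: float, var_mp: float) -> IvwWeights:
    """Weights for the IVW combination: ``w1 = 4/var_cp``, ``w2 = 1/var_mp``.

    ``0.5*beta_cp_hat`` has variance ``var_cp/4``, hence its inverse-variance
    weight is ``4/var_cp``.
    """
    _require_positive(var_cp=var_cp, var_mp=var_mp)
    return IvwWeights(w1=4.0 / var_cp, w2=1.0 / var_mp)


def ivw_estimate(
    beta_cp: float,
    var_cp: float,
    beta_mp: float,
    var_mp: float,
    cov: float = 0.0,
) -> DerivedEstimate:
    """Inverse-variance-weighted paternal estimate.

    Treats the maternal coefficient as one estimate of the paternal
    coefficient and half the child coefficient as another:

    ``beta_hat = (w1*0.5*beta_cp + w2*beta_mp) / (w1 + w2)``

    with ``w1 = 4/var_cp`` and ``w2 = 1/var_mp``.  With ``var_cp = 4*var_mp``
    the two components carry equal precision and the result is their
    simple mean.  The standard error comes from :func:`ivw_se`.
    """
    _require_finite(beta_cp=beta_cp, beta_mp=beta_mp)
    w = ivw_weights(var_cp, var_mp)
    beta = (w.w1 * 0.5 * beta_cp + w.w2 * beta_mp) / (w.w1 + w.w2)
    se = ivw_se(var_cp, var_mp, cov)
    return DerivedEstimate(
        beta_hat=beta,
        se_hat=se,
        method=DeriveMethod.IVW,
        components=((beta_cp, var_cp), (beta_mp, var_mp), cov),
    )


def ivw_se(var_cp: float, var_mp: float, cov: float = 0.0) -> float:
    """Standard error of the IVW combination.

    ``sqrt((0.5*w1/(w1+w2))^2 * var_cp + (w2/(w1+w2))^2 * var_mp
    + cov * w1*w2/(w1+w2)^2)``.

    The cross term equals the usual ``2*a*b*cov`` for the combination
    coefficients ``a = 0.5*w1/(w1+w2)`` and ``b = w2/(w1+w2)`` (the factor
    ``2 * 0.5`` cancels).  With ``cov = 0`` this reduces to the textbook
    IVW variance ``1/(w1+w2)``.
    """
    w = ivw_weights(var_cp, var_mp)
    s = w.w1 + w.w2
    a = 0.5 * w.w1 / s
    b = w.w2 / s
    radicand = a * a * var_cp + b * b * var_mp + cov * w.w1 * w.w2 / (s * s)
    if not (radicand > 0):
        raise ValidationError(f"IVW variance radicand must be > 0; got {radicand}")
    return math.sqrt(radicand)


def _effective_n(method: DeriveMethod, rec_cp: SnpAssociation, rec_mp: SnpAssociation) -> int:
    # Subtraction: limited by the smaller regression.  IVW: precision-sum
    # convention -- the N at which a single regression of the maternal kind
    # would match the combined precision, n_mp * (w1 + w2) * var_mp.
    if method is DeriveMethod.IVW:
        w = ivw_weights(rec_cp.variance, rec_mp.variance)
        return max(2, round(rec_mp.n * (w.w1 + w.w2) * rec_mp.variance))
    return min(rec_cp.n, rec_mp.n)


def derive_set(
    cp: SummaryStatSet,
    mp: SummaryStatSet,
    method: DeriveMethod | str,
    overlap: OverlapModel | None = None,
    trait_label: str | None = None,
) -> SummaryStatSet:
    """Apply an estimator SNP-by-SNP across two aligned sets.

    ``cp`` and ``mp`` must already share identical snp_id sequences and
    harmonized alleles (run :func:`crossgen.sumstats_io.align_sets` first).
    When ``overlap`` is None the coefficient covariance defaults to zero
    and an :class:`IndependenceAssumedWarning` is emitted, because the
    resulting standard errors are only correct under independence.
    """
    method = DeriveMethod(method)
    if cp.snp_ids() != mp.snp_ids():
        raise ValidationError(
            "input sets are not aligned (snp_id sequences differ); run align_sets first"
        )
    for a, b in zip(cp.records, mp.records):
        if (a.effect_allele, a.other_allele) != (b.effect_allele, b.other_allele):
            raise ValidationError(
                f"{a.snp_id}: alleles not harmonized between sets; run align_sets first"
            )
    if overlap is None:
        warnings.warn(
            "no OverlapModel supplied: covariance set to 0; standard errors "
            "are only correct under independence",
            IndependenceAssumedWarning,
            stacklevel=2,
        )
        intercept_desc = "cov=0 (independence assumed)"
    else:
        intercept_desc = (
            f"intercept={overlap.effective_intercept:.6g} "
            f"(N_S={overlap.n_overlap}, rho={overlap.pheno_correlation})"
        )

    records: list[SnpAssociation] = []
    for rec_cp, rec_mp in zip(cp.records, mp.records):
        cov = 0.0
        if overlap is not None:
            cov = covariance_from_overlap(overlap, rec_cp.se, rec_mp.se)
        if method is DeriveMethod.IVW:
            est = ivw_estimate(rec_cp.beta, rec_cp.variance, rec_mp.beta, rec_mp.variance, cov)
            beta, se = est.beta_hat, est.se_hat
        else:
            beta = subtraction_estimate(rec_cp.beta, rec_mp.beta)
            if method is DeriveMethod.SUBTRACTION_CORRECTED:
                se = subtraction_se_corrected(rec_cp.variance, rec_mp.variance, cov)
            else:
                se = subtraction_se_naive(rec_cp.variance, rec_mp.variance)
        records.append(
            SnpAssociation(
                snp_id=rec_cp.snp_id,
                effect_allele=rec_cp.effect_allele,
                other_allele=rec_cp.other_allele,
                eaf=rec_cp.eaf,
                beta=beta,
                se=se,
                n=_effective_n(method, rec_cp, rec_mp),
            )
        )
    return SummaryStatSet(
        role=Role.DERIVED,
        trait_label=trait_label or f"derived({cp.trait_label},{mp.trait_label})",
        records=records,
        provenance=f"{method.value}; {intercept_desc}; from roles "
        f"({cp.role.value}, {mp.role.value})",
    )
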