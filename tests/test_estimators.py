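"""Estimator formulas: exact arithmetic, identities, and orderings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossgen import (
    DeriveMethod,
    OverlapModel,
    covariance_from_overlap,
    derive_set,
    ivw_estimate,
    ivw_se,
    ivw_weights,
    subtraction_estimate,
    subtraction_se_corrected,
    subtraction_se_naive,
)
from crossgen.estimators import IndependenceAssumedWarning
from crossgen.sumstats_io import Role, ValidationError

from conftest import make_set, snp

REL12 = 1e-12

_variances = st.floats(1e-6, 1.0)


class TestSubtraction:
    def test_worked_example(self):
        assert subtraction_estimate(0.10, 0.04) == pytest.approx(0.06, rel=REL12)

    @given(x=st.floats(-10, 10, allow_nan=False))
    @settings(derandomize=True)
    def test_self_subtraction_is_zero(self, x):
        assert subtraction_estimate(x, x) == 0.0

    def test_sign_case(self):
        assert subtraction_estimate(0.0, -0.03) == pytest.approx(0.03, rel=REL12)

    def test_role_symmetry(self):
        # Deriving "maternal" from (child, paternal) is the same code path.
        assert subtraction_estimate(0.1, 0.07) == -subtraction_estimate(0.07, 0.1)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            subtraction_estimate(math.nan, 0.0)

    def test_naive_se_worked_example(self):
        assert subtraction_se_naive(0.0009, 0.0016) == pytest.approx(0.05, rel=REL12)

    def test_naive_se_small_var_limit(self):
        v = 0.0007
        assert subtraction_se_naive(v, 1e-300) == pytest.approx(math.sqrt(v), rel=1e-9)

    def test_corrected_se_worked_example(self):
        got = subtraction_se_corrected(0.0009, 0.0016, 0.0005)
        assert got == pytest.approx(math.sqrt(0.0015), rel=REL12)

    @given(v1=_variances, v2=_variances)
    @settings(derandomize=True)
    def test_corrected_equals_naive_at_zero_cov(self, v1, v2):
        assert subtraction_se_corrected(v1, v2, 0.0) == subtraction_se_naive(v1, v2)

    @given(v1=_variances, v2=_variances, frac=st.floats(0.01, 0.99))
    @settings(derandomize=True)
    def test_positive_cov_shrinks_se(self, v1, v2, frac):
        cov = frac * math.sqrt(v1 * v2)  # |cov| <= se1*se2 keeps radicand positive
        assert subtraction_se_corrected(v1, v2, cov) < subtraction_se_naive(v1, v2)

    def test_nonpositive_radicand_rejected(self):
        with pytest.raises(ValidationError, match="cov"):
            subtraction_se_corrected(0.0009, 0.0016, 0.01)

    @pytest.mark.parametrize("bad", [0.0, -1e-4])
    def test_nonpositive_variance_rejected(self, bad):
        with pytest.raises(ValidationError):
            subtraction_se_naive(bad, 1e-4)


class TestOverlapCovariance:
    def test_zero_overlap_gives_zero(self):
        m = OverlapModel(n_cp=1000, n_mp=800, n_overlap=0, pheno_correlation=0.9)
        assert covariance_from_overlap(m, 0.5, 0.9) == 0.0

    def test_full_overlap_worked_example(self):
        m = OverlapModel(n_cp=1000, n_mp=1000, n_overlap=1000, pheno_correlation=0.3)
        assert covariance_from_overlap(m, 0.01, 0.01) == pytest.approx(3e-5, rel=REL12)

    def test_supplied_intercept_used_directly(self):
        m = OverlapModel(n_cp=1000, n_mp=1000, intercept=0.12)
        assert covariance_from_overlap(m, 0.01, 0.02) == pytest.approx(
            0.12 * 0.01 * 0.02, rel=REL12
        )

    def test_overlap_exceeding_smaller_sample_rejected(self):
        with pytest.raises(ValidationError):
            OverlapModel(n_cp=1000, n_mp=500, n_overlap=600)

    def test_inconsistent_intercept_rejected(self):
        with pytest.raises(ValidationError, match="intercept"):
            OverlapModel(
                n_cp=1000, n_mp=1000, n_overlap=500, pheno_correlation=0.3, intercept=0.3
            )

    def test_consistent_intercept_accepted(self):
        m = OverlapModel(
            n_cp=1000, n_mp=1000, n_overlap=500, pheno_correlation=0.3, intercept=0.15
        )
        assert m.effective_intercept == pytest.approx(0.15, rel=REL12)


class TestIvw:
    def test_equal_precision_is_simple_mean(self):
        est = ivw_estimate(0.10, 4e-4, 0.05, 1e-4)
        assert est.beta_hat == pytest.approx(0.05, rel=REL12)
        w = ivw_weights(4e-4, 1e-4)
        assert w.w1 == pytest.approx(w.w2, rel=REL12) == pytest.approx(1e4, rel=REL12)

    @given(beta_cp=st.floats(-1, 1), v1=_variances, v2=_variances)
    @settings(derandomize=True)
    def test_consensus_case(self, beta_cp, v1, v2):
        """When both components agree, the estimate is their shared value."""
        est = ivw_estimate(beta_cp, v1, 0.5 * beta_cp, v2)
        assert est.beta_hat == pytest.approx(0.5 * beta_cp, rel=1e-9, abs=1e-15)

    def test_uninformative_maternal_limit(self):
        est = ivw_estimate(0.10, 1e-4, 0.9, 1e8)
        assert est.beta_hat == pytest.approx(0.05, rel=1e-6)

    def test_se_worked_example(self):
        assert ivw_se(4e-4, 1e-4, 0.0) == pytest.approx(math.sqrt(5e-5), rel=REL12)

    def test_zero_cov_identity_random_inputs(self):
        """se(cov=0)^2 == 1/(w1+w2): the textbook IVW variance."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            v1, v2 = rng.uniform(1e-6, 1e-2, size=2)
            w = ivw_weights(v1, v2)
            assert ivw_se(v1, v2, 0.0) ** 2 == pytest.approx(1.0 / (w.w1 + w.w2), rel=REL12)

    @given(v1=_variances, v2=_variances)
    @settings(derandomize=True)
    def test_never_less_precise_than_either_component(self, v1, v2):
        var_ivw = ivw_se(v1, v2, 0.0) ** 2
        assert var_ivw <= min(0.25 * v1, v2) * (1 + 1e-12)

    def test_cross_term_matches_two_ab_cov(self):
        """The printed cross term equals 2*a*b*cov for the combination weights."""
        v1, v2, cov = 3e-4, 2e-4, 5e-5
        w = ivw_weights(v1, v2)
        s = w.w1 + w.w2
        a, b = 0.5 * w.w1 / s, w.w2 / s
        expected = math.sqrt(a * a * v1 + b * b * v2 + 2 * a * b * cov)
        assert ivw_se(v1, v2, cov) == pytest.approx(expected, rel=REL12)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValidationError):
            ivw_estimate(0.1, 0.0, 0.05, 1e-4)


class TestDeriveSet:
    def _pair(self):
        cp = make_set(
            [snp("rs1", beta=0.10, se=0.01), snp("rs2", beta=0.06, se=0.02)],
            role=Role.CHILD_PHENO_CHILD_GENO,
        )
        mp = make_set(
            [snp("rs1", beta=0.04, se=0.012), snp("rs2", beta=0.05, se=0.018)],
            role=Role.MATERNAL_PHENO_CHILD_GENO,
        )
        return cp, mp

    def test_subtraction_is_elementwise(self):
        cp, mp = self._pair()
        with pytest.warns(IndependenceAssumedWarning):
            derived = derive_set(cp, mp, DeriveMethod.SUBTRACTION_NAIVE)
        assert derived.role is Role.DERIVED
        assert [r.beta for r in derived.records] == pytest.approx([0.06, 0.01], rel=REL12)
        assert derived.records[0].se == pytest.approx(
            subtraction_se_naive(0.01**2, 0.012**2), rel=REL12
        )
        assert derived.records[0].n == 1000  # min(n_cp, n_mp)

    def test_corrected_se_smaller_with_positive_overlap(self):
        cp, mp = self._pair()
        overlap = OverlapModel(n_cp=1000, n_mp=1000, n_overlap=500, pheno_correlation=0.3)
        naive = derive_set(cp, mp, DeriveMethod.SUBTRACTION_NAIVE, overlap=overlap)
        corrected = derive_set(cp, mp, DeriveMethod.SUBTRACTION_CORRECTED, overlap=overlap)
        for rn, rc in zip(naive.records, corrected.records):
            assert rc.se < rn.se

    def test_warning_when_overlap_absent(self):
        cp, mp = self._pair()
        with pytest.warns(IndependenceAssumedWarning, match="independence"):
            derive_set(cp, mp, DeriveMethod.IVW)

    def test_unaligned_inputs_rejected(self):
        cp, mp = self._pair()
        mp_reordered = make_set(list(reversed(mp.records)), role=mp.role)
        with pytest.raises(ValidationError, match="align_sets"):
            derive_set(cp, mp_reordered, DeriveMethod.SUBTRACTION_NAIVE)

    def test_provenance_records_method(self):
        cp, mp = self._pair()
        overlap = OverlapModel(n_cp=1000, n_mp=1000, n_overlap=500, pheno_correlation=0.3)
        derived = derive_set(cp, mp, DeriveMethod.IVW, overlap=overlap)
        assert "ivw" in derived.provenance
        assert "N_S=500" in derived.provenance
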