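"""IO round trips, row validation, and allele harmonization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossgen import Role, SnpAssociation, align_sets, read_sumstats, write_sumstats
from crossgen.sumstats_io import (
    AlignmentReport,
    EmptyIntersectionError,
    ReadReport,
    SumstatsFormatError,
    ValidationError,
)

from conftest import make_set, snp


class TestSnpAssociationInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(se=0.0),
            dict(se=-0.01),
            dict(eaf=0.0),
            dict(eaf=1.0),
            dict(ea="A", oa="A"),
            dict(ea="N"),
            dict(n=1),
            dict(beta=math.inf),
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            snp(**kwargs)

    def test_missing_eaf_tolerated(self):
        rec = snp(eaf=None)
        assert rec.eaf is None

    def test_duplicate_snp_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            make_set([snp("rs1"), snp("rs1")])

    def test_derived_role_requires_provenance(self):
        with pytest.raises(ValidationError, match="provenance"):
            make_set([snp()], role=Role.DERIVED, provenance="")


class TestReadWrite:
    def test_round_trip_identity(self, three_snp_set, tmp_path):
        path = write_sumstats(three_snp_set, tmp_path / "s.tsv")
        back = read_sumstats(path, three_snp_set.role)
        assert back.snp_ids() == three_snp_set.snp_ids()
        for a, b in zip(three_snp_set.records, back.records):
            assert b.effect_allele == a.effect_allele
            assert b.other_allele == a.other_allele
            assert b.n == a.n
            # 12-significant-digit contract (achieved bit-exactly via 17g)
            assert b.beta == pytest.approx(a.beta, rel=1e-12, abs=1e-300)
            assert b.se == pytest.approx(a.se, rel=1e-12)
            assert b.eaf == pytest.approx(a.eaf, rel=1e-12)
        assert back.records[1].beta == pytest.approx(-0.0123456789012, rel=1e-12)

    def test_input_order_preserved(self, three_snp_set, tmp_path):
        path = write_sumstats(three_snp_set, tmp_path / "s.tsv")
        assert read_sumstats(path, Role.CHILD_PHENO_CHILD_GENO).snp_ids() == [
            "rs1",
            "rs2",
            "rs3",
        ]

    def test_missing_se_column_names_it(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("SNP\tEA\tOA\tEAF\tBETA\tN\nrs1\tA\tG\t0.3\t0.1\t1000\n")
        with pytest.raises(SumstatsFormatError, match="SE"):
            read_sumstats(p, Role.CHILD_PHENO_CHILD_GENO)

    def test_bad_row_rejected_others_kept(self, tmp_path):
        p = tmp_path / "rows.tsv"
        p.write_text(
            "SNP\tEA\tOA\tEAF\tBETA\tSE\tN\n"
            "rs1\tA\tG\t0.3\t0.1\t0.01\t1000\n"
            "rs2\tA\tG\t0.3\t0.1\t0\t1000\n"  # se = 0 -> invalid
            "rs3\tA\tG\t0.3\t0.1\t0.02\t1000\n"
        )
        report = ReadReport()
        got = read_sumstats(p, Role.CHILD_PHENO_CHILD_GENO, report=report)
        assert got.snp_ids() == ["rs1", "rs3"]
        assert report.n_rejected == 1
        assert report.rejected[0].snp_id == "rs2"

    def test_non_numeric_beta_is_row_level(self, tmp_path):
        p = tmp_path / "rows.tsv"
        p.write_text(
            "SNP\tEA\tOA\tEAF\tBETA\tSE\tN\n"
            "rs1\tA\tG\t0.3\txyz\t0.01\t1000\n"
            "rs2\tA\tG\t0.3\t0.1\t0.01\t1000\n"
        )
        report = ReadReport()
        got = read_sumstats(p, Role.CHILD_PHENO_CHILD_GENO, report=report)
        assert got.snp_ids() == ["rs2"]
        assert report.n_rejected == 1

    def test_blank_eaf_read_as_absent(self, tmp_path):
        p = tmp_path / "noeaf.tsv"
        p.write_text("SNP\tEA\tOA\tEAF\tBETA\tSE\tN\nrs1\tA\tG\t\t0.1\t0.01\t1000\n")
        got = read_sumstats(p, Role.CHILD_PHENO_CHILD_GENO)
        assert got.records[0].eaf is None

    def test_empty_set_write_refused(self, tmp_path):
        empty = make_set([])
        with pytest.raises(ValidationError):
            write_sumstats(empty, tmp_path / "never.tsv")
        assert not (tmp_path / "never.tsv").exists()


class TestAlignSets:
    def test_identical_panels_unchanged(self, three_snp_set):
        report = AlignmentReport()
        a2, b2 = align_sets(three_snp_set, three_snp_set, report)
        assert a2.snp_ids() == b2.snp_ids() == three_snp_set.snp_ids()
        assert report.n_dropped_alleles == 0 and report.n_flipped == 0

    def test_swapped_alleles_negate_beta_and_flip_eaf(self):
        a = make_set([snp("rs1", "A", "G", 0.3, 0.1)])
        b = make_set([snp("rs1", "G", "A", 0.7, 0.2)])
        _, b2 = align_sets(a, b)
        rec = b2.records[0]
        assert rec.effect_allele == "A" and rec.other_allele == "G"
        assert rec.beta == pytest.approx(-0.2, rel=1e-15)
        assert rec.eaf == pytest.approx(0.3, rel=1e-12)

    def test_irreconcilable_alleles_dropped_and_counted(self):
        a = make_set([snp("rs1", "A", "G"), snp("rs2", "A", "G")])
        b = make_set([snp("rs1", "C", "T"), snp("rs2", "A", "G")])
        report = AlignmentReport()
        a2, b2 = align_sets(a, b, report)
        assert a2.snp_ids() == ["rs2"]
        assert report.n_dropped_alleles == 1

    def test_palindromic_kept_when_eaf_same_side(self):
        a = make_set([snp("rs1", "A", "T", eaf=0.2)])
        b = make_set([snp("rs1", "A", "T", eaf=0.25)])
        a2, _ = align_sets(a, b)
        assert a2.snp_ids() == ["rs1"]

    def test_palindromic_dropped_when_eaf_straddles_half(self):
        a = make_set([snp("rs1", "C", "G", eaf=0.2), snp("rs2", "A", "G")])
        b = make_set([snp("rs1", "C", "G", eaf=0.8), snp("rs2", "A", "G")])
        report = AlignmentReport()
        a2, _ = align_sets(a, b, report)
        assert a2.snp_ids() == ["rs2"]
        assert report.n_dropped_palindromic == 1

    def test_zero_shared_raises(self):
        a = make_set([snp("rs1")])
        b = make_set([snp("rs2")])
        with pytest.raises(EmptyIntersectionError):
            align_sets(a, b)


_snp_strategy = st.builds(
    snp,
    snp_id=st.sampled_from([f"rs{i}" for i in range(8)]),
    ea=st.just("A"),
    oa=st.just("G"),
    eaf=st.floats(0.05, 0.95),
    beta=st.floats(-1, 1, allow_nan=False),
    se=st.floats(0.001, 1.0),
)


def _dedupe(records):
    seen, out = set(), []
    for r in records:
        if r.snp_id not in seen:
            seen.add(r.snp_id)
            out.append(r)
    return out


@settings(max_examples=50, derandomize=True)
@given(
    ra=st.lists(_snp_strategy, min_size=1, max_size=8),
    rb=st.lists(_snp_strategy, min_size=1, max_size=8),
)
def test_align_is_idempotent_and_symmetric_in_intersection(ra, rb):
    """Aligning twice changes nothing; the shared-SNP set is order-agnostic."""
    a, b = make_set(_dedupe(ra)), make_set(_dedupe(rb), label="other")
    if not set(a.snp_ids()) & set(b.snp_ids()):
        return
    a1, b1 = align_sets(a, b)
    a2, b2 = align_sets(a1, b1)
    assert a2.snp_ids() == a1.snp_ids()
    assert [r.beta for r in b2.records] == [r.beta for r in b1.records]
    bswap, aswap = align_sets(b, a)
    assert set(bswap.snp_ids()) == set(a1.snp_ids())
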