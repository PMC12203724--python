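"""Reading, writing, validating, and harmonizing GWAS summary statistics.

The interchange dialect is a tab-delimited text file with one canonical
header -- ``SNP EA OA EAF BETA SE N`` (case-insensitive on read) -- a ``.``
decimal separator and no quoting.  It resembles an LDSC ``.sumstats`` file
except that effect sizes are carried as BETA/SE rather than Z.  Every other
module exchanges :class:`SummaryStatSet` values through this layer.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Role",
    "SnpAssociation",
    "SummaryStatSet",
    "SumstatsFormatError",
    "ValidationError",
    "EmptyIntersectionError",
    "read_sumstats",
    "write_sumstats",
    "align_sets",
    "AlignmentReport",
]

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

_CANONICAL_COLUMNS = ["SNP", "EA", "OA", "EAF", "BETA", "SE", "N"]


class SumstatsFormatError(ValueError):
    """A summary-statistics file violates the column contract."""


class ValidationError(ValueError):
    """A value violates a domain-type invariant."""


class EmptyIntersectionError(ValueError):
    """Two summary-statistic sets share no usable SNPs."""


class Role(str, enum.Enum):
    """Which (phenotype, genotype) pairing a set of statistics estimates.

    The three concrete roles correspond to the population regression
    coefficients of child / maternal / paternal phenotype on *child*
    genotype; ``DERIVED`` marks sets produced by an estimator rather than
    a regression.
    """

    CHILD_PHENO_CHILD_GENO = "child_pheno_child_geno"
    MATERNAL_PHENO_CHILD_GENO = "maternal_pheno_child_geno"
    PATERNAL_PHENO_CHILD_GENO = "paternal_pheno_child_geno"
    DERIVED = "derived"


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's regression summary for one generational role.

    ``beta`` is in phenotype units per effect-allele count (dosage coded
    0/1/2 as the count of effect alleles, project-wide).  ``eaf`` may be
    ``None``: many public statistics lack allele frequencies, and only
    operations that actually need the frequency reject its absence.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    n: int
    eaf: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be non-empty")
        for name, a in (("effect_allele", self.effect_allele), ("other_allele", self.other_allele)):
            if a not in _VALID_ALLELES:
                raise ValidationError(f"{name} must be one of A,C,G,T; got {a!r}")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta must be finite")
        if self.degenerate:
            if self.se < 0 or not math.isfinite(self.se):
                raise ValidationError(f"{self.snp_id}: degenerate se must be finite and >= 0")
        elif not (self.se > 0 and math.isfinite(self.se)):
            raise ValidationError(f"{self.snp_id}: se must be finite and > 0; got {self.se}")
        if int(self.n) != self.n or self.n < 2:
            raise ValidationError(f"{self.snp_id}: n must be an integer >= 2; got {self.n}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.snp_id}: eaf must lie in (0,1); got {self.eaf}")

    @property
    def variance(self) -> float:
        """Sampling variance of beta (se squared)."""
        return self.se * self.se

    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in _PALINDROMIC_PAIRS

    def flipped(self) -> "SnpAssociation":
        """Return the record expressed on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class SummaryStatSet:
    """A labelled, ordered collection of :class:`SnpAssociation` records."""

    role: Role
    trait_label: str
    records: list[SnpAssociation]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate snp_id {dup!r} within a SummaryStatSet")
        if self.role is Role.DERIVED and not self.provenance:
            raise ValidationError("role=derived requires a non-empty provenance")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Canonical-column DataFrame view (EAF blank where absent)."""
        return pd.DataFrame(
            {
                "SNP": [r.snp_id for r in self.records],
                "EA": [r.effect_allele for r in self.records],
                "OA": [r.other_allele for r in self.records],
                "EAF": [r.eaf for r in self.records],
                "BETA": [r.beta for r in self.records],
                "SE": [r.se for r in self.records],
                "N": [r.n for r in self.records],
            }
        )


@dataclass
class RowReport:
    """Outcome of parsing one input row that failed validation."""

    line: int
    snp_id: str
    reason: str


@dataclass
class ReadReport:
    """Per-row rejection report accompanying a parsed set."""

    rejected: list[RowReport] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_sumstats(
    path: str | Path,
    role: Role | str,
    trait_label: str | None = None,
    report: ReadReport | None = None,
) -> SummaryStatSet:
    """Parse a tab-delimited summary-statistics file.

    Rows violating the :class:`SnpAssociation` invariants (non-positive SE,
    frequency outside (0,1), malformed alleles, non-numeric fields) are
    rejected individually; pass a :class:`ReadReport` to receive the per-row
    reasons.  Input order is preserved.

    Raises
    ------
    SumstatsFormatError
        If a mandatory column (SNP, EA, OA, BETA, SE, N) is missing.  EAF
        is tolerated as absent.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().upper() for c in df.columns]
    mandatory = ["SNP", "EA", "OA", "BETA", "SE", "N"]
    for col in mandatory:
        if col not in df.columns:
            raise SumstatsFormatError(f"{path}: missing mandatory column {col!r}")
    has_eaf = "EAF" in df.columns

    records: list[SnpAssociation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        get = lambda col: getattr(row, col)
        snp_id = str(get("SNP")).strip()
        try:
            eaf_raw = get("EAF") if has_eaf else None
            eaf = None
            if eaf_raw is not None and str(eaf_raw).strip() not in ("", ".", "NA", "nan"):
                eaf = float(eaf_raw)
            rec = SnpAssociation(
                snp_id=snp_id,
                effect_allele=str(get("EA")).strip().upper(),
                other_allele=str(get("OA")).strip().upper(),
                eaf=eaf,
                beta=float(get("BETA")),
                se=float(get("SE")),
                n=int(float(get("N"))),
            )
        except (ValidationError, ValueError, TypeError) as exc:
            if report is not None:
                report.rejected.append(RowReport(line=line, snp_id=snp_id, reason=str(exc)))
            continue
        records.append(rec)

    return SummaryStatSet(
        role=Role(role),
        trait_label=trait_label if trait_label is not None else path.stem,
        records=records,
        provenance=f"read from {path.name}",
    )


def write_sumstats(stats: SummaryStatSet, path: str | Path) -> Path:
    """Write a set in the canonical tab-delimited dialect.

    Floats are rendered with 17 significant digits so that a read/write
    round trip reproduces every field to at least 12 significant digits
    (in practice bit-exactly for IEEE doubles).
    """
    if len(stats.records) == 0:
        raise ValidationError("refusing to write an empty SummaryStatSet")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_CANONICAL_COLUMNS) + "\n")
        for r in stats.records:
            eaf = "" if r.eaf is None else format(r.eaf, ".17g")
            fh.write(
                f"{r.snp_id}\t{r.effect_allele}\t{r.other_allele}\t{eaf}\t"
                f"{format(r.beta, '.17g')}\t{format(r.se, '.17g')}\t{r.n}\n"
            )
    return path


@dataclass
class AlignmentReport:
    """Counts of SNPs dropped during harmonization, by reason."""

    n_shared: int = 0
    n_flipped: int = 0
    n_dropped_alleles: int = 0
    n_dropped_palindromic: int = 0


def _harmonize_pair(
    ra: SnpAssociation, rb: SnpAssociation, report: AlignmentReport
) -> SnpAssociation | None:
    """Express ``rb`` on ``ra``'s effect allele, or None if irreconcilable."""
    if (rb.effect_allele, rb.other_allele) == (ra.effect_allele, ra.other_allele):
        candidate, flipped = rb, False
    elif (rb.effect_allele, rb.other_allele) == (ra.other_allele, ra.effect_allele):
        candidate, flipped = rb.flipped(), True
    else:
        report.n_dropped_alleles += 1
        return None
    if ra.is_palindromic():
        # A/T and C/G sites: a strand flip is indistinguishable from an
        # allele swap, so keep the SNP only when both frequencies sit on
        # the same side of 0.5 (standard two-sample MR practice).
        if ra.eaf is None or candidate.eaf is None:
            report.n_dropped_palindromic += 1
            return None
        if (ra.eaf - 0.5) * (candidate.eaf - 0.5) <= 0:
            report.n_dropped_palindromic += 1
            return None
    if flipped:
        report.n_flipped += 1
    return candidate


def align_sets(
    a: SummaryStatSet,
    b: SummaryStatSet,
    report: AlignmentReport | None = None,
) -> tuple[SummaryStatSet, SummaryStatSet]:
    """Restrict two sets to shared SNPs with alleles harmonized to ``a``.

    Where ``b``'s effect allele equals ``a``'s other allele the record is
    flipped (beta negated, eaf complemented).  SNPs whose allele pairs
    neither match nor swap are dropped and counted, as are palindromic
    SNPs whose frequencies cannot resolve the strand.  The returned sets
    carry identical snp_id sequences in ``a``'s input order.
    """
    if report is None:
        report = AlignmentReport()
    b_by_id = {r.snp_id: r for r in b.records}
    out_a: list[SnpAssociation] = []
    out_b: list[SnpAssociation] = []
    for ra in a.records:
        rb = b_by_id.get(ra.snp_id)
        if rb is None:
            continue
        harm = _harmonize_pair(ra, rb, report)
        if harm is None:
            continue
        out_a.append(ra)
        out_b.append(harm)
    if not out_a:
        raise EmptyIntersectionError(
            f"no usable shared SNPs between {a.trait_label!r} and {b.trait_label!r}"
        )
    report.n_shared = len(out_a)
    mk = lambda s, recs: SummaryStatSet(
        role=s.role,
        trait_label=s.trait_label,
        records=recs,
        provenance=(s.provenance + "; " if s.provenance else "") + "aligned",
    )
    return mk(a, out_a), mk(b, out_b)
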