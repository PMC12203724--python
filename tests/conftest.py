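import numpy as np
import pytest

from crossgen import Role, SnpAssociation, SummaryStatSet


@pytest.fixture
def ols_oracle():
    """Independent least-squares oracle: statsmodels OLS with intercept.

    Returns (beta, se) of the first non-intercept column.
    """
    import statsmodels.api as sm

    def fit(y, X):
        model = sm.OLS(np.asarray(y, dtype=float), sm.add_constant(np.asarray(X, dtype=float)))
        res = model.fit()
        return float(res.params[1]), float(res.bse[1])

    return fit


def make_set(records, role=Role.CHILD_PHENO_CHILD_GENO, label="trait", provenance=""):
    return SummaryStatSet(role=role, trait_label=label, records=list(records), provenance=provenance)


def snp(snp_id="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01, n=1000):
    return SnpAssociation(
        snp_id=snp_id, effect_allele=ea, other_allele=oa, eaf=eaf, beta=beta, se=se, n=n
    )


@pytest.fixture
def three_snp_set():
    return make_set(
        [
            snp("rs1", "A", "G", 0.3, 0.10, 0.010, 1000),
            snp("rs2", "C", "T", 0.45, -0.0123456789012, 0.020, 1500),
            snp("rs3", "G", "A", 0.2, 0.0, 0.015, 900),
        ]
    )
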