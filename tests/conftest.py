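"""Shared fixtures: tiny hand-built summary statistics and harmonized sets."""

import numpy as np
import pandas as pd
import pytest

from mrmediate import AssocRecord, HarmonizedSet, SumStats, VariantKey


def make_record(
    rsid,
    beta,
    se,
    pval,
    ea="A",
    oa="G",
    chrom="1",
    pos=1,
    eaf=None,
    n=None,
):
    return AssocRecord(
        key=VariantKey(rsid, chrom, pos),
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        pval=pval,
        eaf=eaf,
        n=n,
    )


def make_sumstats(trait_id, rows, trait_type="quantitative"):
    """rows: iterable of dicts passed to make_record."""
    return SumStats(trait_id, trait_type, [make_record(**r) for r in rows])


def make_harmonized(beta_exp, se_exp, beta_out, se_out, exposure="x", outcome="y"):
    beta_exp = np.asarray(beta_exp, float)
    n = len(beta_exp)
    table = pd.DataFrame(
        {
            "rsid": [f"rs{i + 1}" for i in range(n)],
            "beta_exp": beta_exp,
            "se_exp": np.broadcast_to(np.asarray(se_exp, float), (n,)).copy(),
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.broadcast_to(np.asarray(se_out, float), (n,)).copy(),
            "flipped": False,
        }
    )
    return HarmonizedSet(exposure, outcome, table)


@pytest.fixture
def three_snp_harmonized():
    """The 3-SNP instance with all ratio SEs equal to 0.1."""
    return make_harmonized(
        beta_exp=[0.1, 0.2, 0.4],
        se_exp=0.01,
        beta_out=[0.05, 0.08, 0.22],
        se_out=[0.01, 0.02, 0.04],
    )


@pytest.fixture
def proportional_harmonized():
    """Ten exactly proportional SNPs (beta_out = 0.5 * beta_exp)."""
    rng = np.random.default_rng(5)
    bx = rng.uniform(0.1, 0.3, size=10) * rng.choice([-1.0, 1.0], size=10)
    return make_harmonized(bx, 0.01, 0.5 * bx, 0.02)
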