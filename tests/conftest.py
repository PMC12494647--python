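import numpy as np
import pytest

from pqtlmr.harmonise import HarmonisedRecord, HarmonisedSet
from pqtlmr.sumstats import VariantAssoc


def make_assoc(
    chrom="1",
    pos=100,
    ea="A",
    oa="G",
    beta=0.1,
    se=0.02,
    pval=1e-9,
    eaf=0.3,
    n=10_000,
    variant_id="rs1",
):
    return VariantAssoc(
        variant_id=variant_id, chrom=chrom, pos=pos, effect_allele=ea,
        other_allele=oa, beta=beta, se=se, pval=pval, eaf=eaf, n=n,
    )


def make_hset(beta_exp, se_exp, beta_out, se_out, protein_id="P1", outcome="out"):
    hs = HarmonisedSet(protein_id=protein_id, outcome_label=outcome)
    for i, (be, se_e, bo, so) in enumerate(zip(beta_exp, se_exp, beta_out, se_out)):
        hs.records.append(
            HarmonisedRecord(
                key=f"1:{100 + i}", beta_exp=be, se_exp=se_e, beta_out=bo, se_out=so
            )
        )
    return hs


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def random_hset(rng):
    """Moderate-size harmonised set with a true causal slope of 0.3."""
    k = 8
    be = rng.uniform(0.1, 0.5, k)
    se_e = np.full(k, 0.02)
    bo = 0.3 * be + rng.normal(0, 0.01, k)
    so = np.full(k, 0.01)
    return make_hset(be, se_e, bo, so)
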