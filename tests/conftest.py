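import numpy as np
import pytest

from proteomr.simulate import demo_config, simulate_hf_cohort_and_outcome_gwas
from proteomr.sumstats import AssociationRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240229)


def make_record(
    variant_id="rs1",
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pvalue=1e-6,
    n=10000,
    trait_id="t",
):
    return AssociationRecord(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
        trait_id=trait_id,
    )


@pytest.fixture(scope="session")
def demo_bundle():
    """One reference synthetic study, shared across pipeline tests."""
    return simulate_hf_cohort_and_outcome_gwas(demo_config(seed=11))
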