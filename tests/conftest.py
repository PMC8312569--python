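import numpy as np
import pytest

from ivmr.harmonize import HarmonizedVariant
from ivmr.sumstats_io import VariantAssociation


def make_variant(
    variant_id="rs1",
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    beta=0.1,
    se=0.01,
    pval=1e-10,
    n=77_000,
    eaf=0.3,
):
    return VariantAssociation(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
        eaf=eaf,
    )


def hv(variant_id, gamma, se_x, Gamma, se_y, **kw):
    return HarmonizedVariant(
        variant_id=variant_id, gamma=gamma, se_x=se_x, Gamma=Gamma, se_y=se_y, **kw
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def affine_instruments(rng):
    """Instruments whose outcome effects are exactly 0.05 + 0.2 * gamma."""
    gammas = rng.uniform(0.05, 0.2, size=10)
    return [
        hv(f"rs{i}", g, 0.01, 0.05 + 0.2 * g, 0.1) for i, g in enumerate(gammas)
    ]
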