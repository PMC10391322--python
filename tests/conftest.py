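import numpy as np
import pytest

from cytomr import HarmonisedSet, SummaryStatRecord


def mk_record(
    vid="rs1",
    ea="A",
    oa="G",
    beta=0.1,
    se=0.01,
    chrom="1",
    pos=1_000_000,
    eaf=0.3,
    pvalue=None,
    n=8000.0,
):
    from cytomr.gwas_io import two_sided_p

    return SummaryStatRecord(
        variant_id=vid,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=two_sided_p(beta, se) if pvalue is None else pvalue,
        n=n,
    )


def random_pairs(rng: np.random.Generator, k: int) -> HarmonisedSet:
    """A random harmonised set with positive-signed exposure betas allowed to vary."""
    bx = rng.uniform(0.05, 0.6, size=k) * rng.choice([-1.0, 1.0], size=k)
    sx = rng.uniform(0.005, 0.05, size=k)
    by = rng.normal(0.0, 0.1, size=k)
    sy = rng.uniform(0.005, 0.05, size=k)
    return HarmonisedSet.from_arrays(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
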