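import numpy as np
import pytest
from hypothesis import settings

from imkt.types import DafBin, DafTable, DivergenceSummary, GeneRecord

settings.register_profile("default", derandomize=True, database=None)
settings.load_profile("default")


def make_gene(gene_id="g", bins=((0.25, 5, 5),), dn=5, ds=5, m_n=None, m_s=None,
              n_sample=4, **metadata):
    return GeneRecord(
        gene_id=gene_id,
        daf=DafTable(n_sample=n_sample, bins=[DafBin(*b) for b in bins]),
        div=DivergenceSummary(dn=dn, ds=ds, m_n=m_n, m_s=m_s),
        metadata=dict(metadata),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_daf_table(rng, n_sample=None, max_count=40):
    """A random valid spectrum on the full i/n frequency grid."""
    if n_sample is None:
        n_sample = int(rng.integers(4, 25))
    bins = [
        DafBin(i / n_sample, int(rng.integers(0, max_count)), int(rng.integers(0, max_count)))
        for i in range(1, n_sample)
    ]
    return DafTable(n_sample=n_sample, bins=bins)


def random_divergence(rng, max_count=60, with_sites=True):
    dn = int(rng.integers(0, max_count))
    ds = int(rng.integers(0, max_count))
    if with_sites:
        return DivergenceSummary(dn=dn, ds=ds, m_n=dn + float(rng.integers(50, 500)),
                                 m_s=ds + float(rng.integers(50, 500)))
    return DivergenceSummary(dn=dn, ds=ds)
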