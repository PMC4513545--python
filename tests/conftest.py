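import numpy as np
import pytest

from liabkit.io_formats import GenotypeMatrix, SnpRecord


def make_gm(dosages, chromosomes=None, positions=None):
    """GenotypeMatrix from a raw dosage array with auto-generated metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    chromosomes = chromosomes if chromosomes is not None else [1] * m
    positions = positions if positions is not None else [(j + 1) * 1000 for j in range(m)]
    snps = [
        SnpRecord(id=f"snp{j + 1}", chromosome=int(chromosomes[j]),
                  position=int(positions[j]), allele1="A", allele2="G")
        for j in range(m)
    ]
    samples = [(f"F{i + 1}", f"I{i + 1}") for i in range(n)]
    return GenotypeMatrix(samples, snps, dosages)


def random_gm(rng, n, m, missing_rate=0.0, maf_low=0.1, maf_high=0.5, **kw):
    p = rng.uniform(maf_low, maf_high, size=m)
    d = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        d[rng.random((n, m)) < missing_rate] = -1
    return make_gm(d, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
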