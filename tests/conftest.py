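import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160517)


def make_reference_like_genotypes(n_ind=38, n_alleles=27, n_het=33,
                                  size_min=140, motif_len=2):
    """Deterministic synthetic stand-in for a deposited genotype column.

    Builds a diploid genotype dict with exactly ``n_alleles`` distinct allele
    labels (a dimer ladder from ``size_min``) and exactly ``n_het``
    heterozygous individuals out of ``n_ind`` — the marginal features of a
    highly polymorphic reference locus — without any external data file.
    """
    labels = [size_min + motif_len * i for i in range(n_alleles)]
    gts = {}
    for i in range(n_ind):
        if i < n_het:
            a = labels[i % n_alleles]
            b = labels[(i + 1) % n_alleles]
            gts[f"ind{i:03d}"] = (min(a, b), max(a, b))
        else:
            a = labels[i % n_alleles]
            gts[f"ind{i:03d}"] = (a, a)
    assert len({x for g in gts.values() for x in g}) == n_alleles
    return gts
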