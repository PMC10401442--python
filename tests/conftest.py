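import numpy as np
import pytest

from breedsim.genome import GeneticMap, HaplotypePopulation, QTLModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_locus_map():
    """Two loci 20 cM apart on one chromosome."""
    return GeneticMap(("chr1",), np.array([0, 2]), np.array([0.0, 20.0]), ("m1", "m2"))


def make_population(dosages, map_=None, ids=None):
    """Population of fully inbred individuals from a dosage matrix in {-1, +1},
    heterozygotes (0) phased arbitrarily."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if map_ is None:
        map_ = GeneticMap.uniform(m, 1, chrom_length_cM=float(10 * max(m - 1, 1)))
    h = np.zeros((n, 2, m), dtype=np.int8)
    h[:, 0, :] = dosages == 1
    h[:, 1, :] = dosages >= 0
    if ids is None:
        ids = np.array([f"i{j:02d}" for j in range(n)], dtype=object)
    return HaplotypePopulation(h, map_, ids)


def make_qtl_model(L, n_loci=None, favorable=None):
    """QTL model with the first L loci as QTLs in k-order 1..L."""
    n_loci = n_loci or L
    a = (L - 1) / (L + 1)
    effects = a ** np.arange(1, L + 1, dtype=float)
    favorable = np.ones(L, dtype=np.int8) if favorable is None else np.asarray(favorable)
    return QTLModel(
        np.arange(L),
        favorable,
        effects,
        np.arange(L, n_loci),
        a,
        float(effects.sum()),
    )
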