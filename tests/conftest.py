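import numpy as np
import pytest

from popgenscan.popio import PopulationMap, VariantTable


def make_table(genotypes, pos=None, chrom="chr1", samples=None,
               contig_length=None):
    """Build a VariantTable from a (sites x samples) genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    samples = samples or [f"s{i}" for i in range(n_samples)]
    lengths = {chrom: contig_length} if contig_length else {}
    return VariantTable(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        genotypes=g, samples=samples, contig_lengths=lengths)


def table_from_haplotypes(haps, pos=None, chrom="chr1", contig_length=None):
    """Diploidize a (sites x haplotypes) 0/1 matrix (consecutive pairing)."""
    h = np.asarray(haps, dtype=np.int8)
    assert h.shape[1] % 2 == 0
    return make_table(h[:, 0::2] + h[:, 1::2], pos, chrom,
                      contig_length=contig_length)


@pytest.fixture
def two_pop_map():
    """4 diploids in popA, 3 in popB, 1 outgroup sample."""
    assignments = {f"s{i}": "popA" for i in range(4)}
    assignments.update({f"s{i}": "popB" for i in range(4, 7)})
    assignments["s7"] = "out"
    return PopulationMap(assignments, {"out"})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
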