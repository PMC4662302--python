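import numpy as np
import pytest

from rangegen.popgen import MISSING, GenotypeTable


@pytest.fixture
def two_pop_fixed():
    """Two populations fixed for different alleles at one locus."""
    calls = np.array([[[1, 1]]] * 4 + [[[2, 2]]] * 4, dtype=np.int32)
    return GenotypeTable(
        individuals=[f"i{k}" for k in range(8)],
        populations=["a"] * 4 + ["b"] * 4,
        loci=["L1"],
        calls=calls,
    )


@pytest.fixture
def all_het_one_pop():
    """One population in which every individual is an A/B heterozygote."""
    calls = np.array([[[1, 2]]] * 6, dtype=np.int32)
    return GenotypeTable(
        individuals=[f"i{k}" for k in range(6)],
        populations=["a"] * 6,
        loci=["L1"],
        calls=calls,
    )


def make_table(pop_genos, loci=None):
    """Build a GenotypeTable from {pop: [(a1, a2) per locus per ind]} dicts.

    ``pop_genos`` maps population label to a list of individuals, each a
    list of (allele1, allele2) tuples (one per locus).
    """
    inds, pops, rows = [], [], []
    count = 0
    for pop, members in pop_genos.items():
        for genos in members:
            inds.append(f"i{count}")
            pops.append(pop)
            rows.append(genos)
            count += 1
    calls = np.array(rows, dtype=np.int32)
    n_loci = calls.shape[1]
    return GenotypeTable(
        individuals=inds, populations=pops,
        loci=loci or [f"L{k}" for k in range(n_loci)], calls=calls,
    )
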