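import numpy as np
import pandas as pd
import pytest

from ventconn.genetic_io import (
    AlignmentRecord,
    LocusAlignment,
    PopulationHierarchy,
)


def make_alignment(seqs, locus="toy", ploidy=1, individuals=None):
    """Build a LocusAlignment from raw sequence strings."""
    records = []
    for i, s in enumerate(seqs):
        ind = individuals[i] if individuals else f"ind{i:03d}"
        records.append(AlignmentRecord(f"seq{i:03d}", ind, 1, s))
    return LocusAlignment(locus, ploidy, records)


@pytest.fixture
def two_pop_hierarchy():
    """10 individuals split into two populations in one region."""
    ind2pop = {f"ind{i:03d}": ("popA" if i < 5 else "popB") for i in range(10)}
    return PopulationHierarchy(ind2pop, {"popA": "r1", "popB": "r1"})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_haplotype_counts(rng, n_pops=2, max_alleles=4, n_min=4, n_max=20):
    """Random allele-count matrix for F_ST oracle tests."""
    k = rng.integers(2, max_alleles + 1)
    while True:
        counts = rng.integers(0, 8, size=(n_pops, k))
        if np.all(counts.sum(axis=1) >= n_min) and np.all(counts.sum(axis=1) <= n_max):
            # need polymorphism overall
            tot = counts.sum(axis=0)
            if np.sum(tot > 0) >= 2:
                return counts
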