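import numpy as np
import pytest

import mixedstock as ms
from mixedstock.haplotypes import HaplotypeCountTable


@pytest.fixture(scope="session")
def reference_table():
    """Bundled Atlantic rookery × haplotype table, mixture MT."""
    return ms.datasets.load_reference_counts()


@pytest.fixture(scope="session")
def reduced_table(reference_table):
    reduced, _ = ms.apply_exclusion_rules(reference_table)
    return reduced


@pytest.fixture(scope="session")
def coastal_mask():
    return ms.make_coastal_mask()


def two_pop_table(counts_a, counts_b, mixture_counts=None, haps=None):
    """Small mixture + two-source table for pairwise statistics tests."""
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    H = len(counts_a)
    if mixture_counts is None:
        mixture_counts = np.ones(H, dtype=np.int64)
    if haps is None:
        haps = [f"h{i + 1}" for i in range(H)]
    return HaplotypeCountTable(
        population_ids=["MIX", "A", "B"],
        haplotype_ids=haps,
        counts=np.vstack([mixture_counts, counts_a, counts_b]),
        mixture_id="MIX",
    )
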