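import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper

from ssrmine.genotype_stats import GenotypeMatrix


def make_matrix(calls: dict[str, list[tuple[int, int]]]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {locus_id: [(a1, a2), ...]} with
    auto-numbered accessions; (0, 0) marks a missing call."""
    locus_ids = list(calls)
    n = len(next(iter(calls.values())))
    data = np.zeros((n, len(locus_ids), 2), dtype=np.int64)
    for j, loc in enumerate(locus_ids):
        if len(calls[loc]) != n:
            raise ValueError("ragged genotype lists")
        data[:, j, :] = calls[loc]
    return GenotypeMatrix([f"acc{i+1}" for i in range(n)], locus_ids, data)


@pytest.fixture
def two_allele_matrix() -> GenotypeMatrix:
    """Three accessions AA, AB, BB at one locus (A=180, B=184)."""
    return make_matrix({"L1": [(180, 180), (180, 184), (184, 184)]})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
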