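"""Presence/absence fingerprints and the panel discrimination rate.

Each (locus, allele) pair becomes a 0/1 column: an accession scores 1 for
every allele it carries (one column for a homozygote, two for a
heterozygote).  Accessions sharing an identical profile are ambiguous; the
discrimination rate is the percentage of accessions whose profile is unique
in the panel.  A group of g indistinguishable accessions contributes all g
members to the ambiguous count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_stats import MISSING, GenotypeMatrix


@dataclass
class FingerprintMatrix:
    accession_ids: list[str]
    columns: list[tuple[str, int]]  # (locus_id, allele label)
    values: np.ndarray  # 0/1, shape (n_accessions, n_columns)
    missing: np.ndarray  # bool, shape (n_accessions, n_loci)
    locus_ids: list[str]

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{loc}:{allele}" for loc, allele in self.columns]
        return pd.DataFrame(self.values, index=self.accession_ids, columns=cols)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="accession")


@dataclass
class DiscriminationReport:
    n_accessions: int
    groups: list[list[str]]  # profile-sharing groups of size >= 2
    n_unambiguous: int
    rate: float  # percent, 2 dp

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_accessions": self.n_accessions,
                    "ambiguous_groups": self.groups,
                    "n_unambiguous": self.n_unambiguous,
                    "discrimination_rate_pct": self.rate,
                },
                fh, indent=2,
            )


def binarize(matrix: GenotypeMatrix) -> FingerprintMatrix:
    """Expand a genotype matrix to one 0/1 column per (locus, allele).

    A missing call leaves that locus's columns all zero for the accession;
    the missing mask is kept so profile comparison can honour it.
    """
    if matrix.n_accessions == 0 or matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    columns: list[tuple[str, int]] = []
    blocks = []
    for j, loc in enumerate(matrix.locus_ids):
        calls = matrix.data[:, j, :]
        alleles = sorted(set(calls.ravel()) - {MISSING})
        block = np.zeros((matrix.n_accessions, len(alleles)), dtype=np.int8)
        for c, allele in enumerate(alleles):
            block[:, c] = (calls == allele).any(axis=1)
        columns.extend((loc, int(a)) for a in alleles)
        blocks.append(block)
    return FingerprintMatrix(
        accession_ids=list(matrix.accession_ids),
        columns=columns,
        values=np.hstack(blocks) if blocks else np.zeros((matrix.n_accessions, 0), np.int8),
        missing=matrix.missing_mask(),
        locus_ids=list(matrix.locus_ids),
    )


def _strict_groups(fp: FingerprintMatrix) -> list[list[int]]:
    keys: dict[bytes, list[int]] = {}
    for i in range(fp.n_accessions):
        key = fp.values[i].tobytes() + fp.missing[i].tobytes()
        keys.setdefault(key, []).append(i)
    return list(keys.values())


def _ignore_missing_groups(fp: FingerprintMatrix) -> list[list[int]]:
    # accessions are compatible when they agree wherever both loci are
    # observed; groups are connected components of the compatibility graph
    n = fp.n_accessions
    col_locus = np.array([fp.locus_ids.index(loc) for loc, _ in fp.columns])
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            both = ~(fp.missing[i] | fp.missing[j])
            cols = both[col_locus]
            if np.array_equal(fp.values[i, cols], fp.values[j, cols]):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def discrimination(
    fp: FingerprintMatrix, treat_missing: str = "strict"
) -> DiscriminationReport:
    """Group accessions by identical profiles and report the rate of
    unambiguous identification.

    ``treat_missing="strict"`` makes missing data part of the profile (two
    accessions differing only in what is missing are distinct);
    ``"ignore"`` lets missing calls wildcard-match, grouping accessions that
    cannot be told apart from their observed loci alone.
    """
    if fp.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    if treat_missing == "strict":
        groups = _strict_groups(fp)
    elif treat_missing == "ignore":
        groups = _ignore_missing_groups(fp)
    else:
        raise ValueError("treat_missing must be 'strict' or 'ignore'")
    dup = [g for g in groups if len(g) >= 2]
    n = fp.n_accessions
    n_unamb = n - sum(len(g) for g in dup)
    return DiscriminationReport(
        n_accessions=n,
        groups=[[fp.accession_ids[i] for i in g] for g in dup],
        n_unambiguous=n_unamb,
        rate=round(100.0 * n_unamb / n, 2),
    )


def discrimination_rate(n_accessions: int, duplicate_group_sizes: list[int]) -> float:
    """Rate (percent, 2 dp) from a panel size and the sizes of its
    indistinguishable groups, e.g. 149 with [2, 2, 2] -> 95.97."""
    n_unamb = n_accessions - sum(duplicate_group_sizes)
    return round(100.0 * n_unamb / n_accessions, 2)
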