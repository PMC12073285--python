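"""Codominant diversity statistics for diploid microsatellite genotypes.

The central container is :class:`GenotypeMatrix`: accessions x loci, each
cell an unordered pair of integer allele labels (fragment sizes in bp), 0
marking a missing call.  Per-locus statistics follow the GenAlEx
conventions used throughout plant germplasm studies:

* ``Na``  observed allele count
* ``Ne``  effective allele count, ``1 / sum(p_i^2)``
* ``I``   Shannon's information index, ``-sum(p_i ln p_i)``
* ``Ho``  observed heterozygosity (fraction of heterozygous accessions)
* ``He``  expected heterozygosity (Nei's gene diversity, ``1 - sum(p_i^2)``)
* ``F``   fixation index, ``(He - Ho) / He``
* ``PIC`` polymorphism information content (Botstein form, the quantity
  Cervus reports): ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``

Missing calls are excluded locus-wise (pairwise deletion), so per-locus N
may vary across a panel.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0  # allele-label sentinel

STAT_COLUMNS = ["N", "Na", "Ne", "I", "Ho", "He", "F", "PIC"]


class GenotypeMatrix:
    """Accessions x loci diploid calls with integer allele labels.

    ``data`` has shape (n_accessions, n_loci, 2); allele label 0 is the
    missing sentinel and a call is missing iff either label is 0.
    """

    def __init__(
        self,
        accession_ids: Sequence[str],
        locus_ids: Sequence[str],
        data: np.ndarray,
    ):
        accession_ids = list(accession_ids)
        locus_ids = list(locus_ids)
        if len(set(accession_ids)) != len(accession_ids):
            raise ValueError("duplicate accession ids")
        if len(set(locus_ids)) != len(locus_ids):
            raise ValueError("duplicate locus ids")
        data = np.asarray(data, dtype=np.int64)
        if data.shape != (len(accession_ids), len(locus_ids), 2):
            raise ValueError("data shape must be (n_accessions, n_loci, 2)")
        if (data < 0).any():
            raise ValueError("allele labels must be >= 0 (0 = missing)")
        # half-missing calls are treated as fully missing
        half = (data == MISSING).any(axis=2)
        data = data.copy()
        data[half] = MISSING
        self.accession_ids = accession_ids
        self.locus_ids = locus_ids
        self.data = data
        self._acc_index = {a: i for i, a in enumerate(accession_ids)}
        self._loc_index = {l: j for j, l in enumerate(locus_ids)}

    # -- basic access -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def calls(self, locus_id: str) -> np.ndarray:
        """(n_accessions, 2) allele labels at one locus."""
        return self.data[:, self._loc_index[locus_id], :]

    def subset_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._acc_index[a] for a in ids]
        return GenotypeMatrix(list(ids), self.locus_ids, self.data[idx])

    def missing_mask(self) -> np.ndarray:
        """(n_accessions, n_loci) boolean, True where the call is missing."""
        return (self.data == MISSING).all(axis=2)

    # -- GenAlEx-style CSV I/O -----------------------------------------
    def to_genalex_csv(self, path, grouping: Mapping[str, str] | None = None,
                       title: str = "ssrmine export") -> None:
        """Write the codominant GenAlEx layout (three header rows, two
        columns per locus, 0 = missing)."""
        pops = [grouping.get(a, "pop1") if grouping else "pop1"
                for a in self.accession_ids]
        pop_order = list(dict.fromkeys(pops))
        sizes = [pops.count(p) for p in pop_order]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([self.n_loci, self.n_accessions, len(pop_order), *sizes])
            w.writerow([title, "", "", *pop_order])
            header = ["Sample", "Pop"]
            for loc in self.locus_ids:
                header += [loc, ""]
            w.writerow(header)
            order = sorted(range(self.n_accessions), key=lambda i: pop_order.index(pops[i]))
            for i in order:
                row = [self.accession_ids[i], pops[i]]
                for j in range(self.n_loci):
                    row += [int(self.data[i, j, 0]), int(self.data[i, j, 1])]
                w.writerow(row)

    @classmethod
    def from_genalex_csv(cls, path) -> tuple["GenotypeMatrix", dict[str, str]]:
        """Read the layout written by :meth:`to_genalex_csv`; returns the
        matrix and the accession -> population grouping."""
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        n_loci = int(rows[0][0])
        header = rows[2]
        locus_ids = [header[2 + 2 * j] for j in range(n_loci)]
        acc_ids, grouping, data = [], {}, []
        for row in rows[3:]:
            if not row or not row[0]:
                continue
            acc_ids.append(row[0])
            grouping[row[0]] = row[1]
            vals = [int(float(x)) if x else MISSING for x in row[2 : 2 + 2 * n_loci]]
            data.append(np.array(vals).reshape(n_loci, 2))
        return cls(acc_ids, locus_ids, np.array(data)), grouping

    # -- long-format TSV -------------------------------------------------
    def to_long_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["accession", "locus", "allele1", "allele2"])
            for i, acc in enumerate(self.accession_ids):
                for j, loc in enumerate(self.locus_ids):
                    w.writerow([acc, loc, int(self.data[i, j, 0]),
                                int(self.data[i, j, 1])])

    @classmethod
    def from_long_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        acc_ids = list(dict.fromkeys(df["accession"]))
        locus_ids = list(dict.fromkeys(df["locus"]))
        data = np.zeros((len(acc_ids), len(locus_ids), 2), dtype=np.int64)
        ai = {a: i for i, a in enumerate(acc_ids)}
        li = {l: j for j, l in enumerate(locus_ids)}
        for row in df.itertuples(index=False):
            data[ai[row.accession], li[row.locus]] = (row.allele1, row.allele2)
        return cls(acc_ids, locus_ids, data)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def allele_frequencies(matrix: GenotypeMatrix, locus_id: str) -> dict[int, float]:
    """Allele relative frequencies at one locus over non-missing calls."""
    calls = matrix.calls(locus_id)
    ok = (calls != MISSING).all(axis=1)
    if not ok.any():
        raise ValueError(f"locus {locus_id}: all calls missing")
    alleles, counts = np.unique(calls[ok].ravel(), return_counts=True)
    total = counts.sum()
    return {int(a): c / total for a, c in zip(alleles, counts)}


def pic_botstein(p: Sequence[float]) -> float:
    """Polymorphism information content, ``1 - S2 - (S2^2 - S4)`` with
    ``S2 = sum p^2`` and ``S4 = sum p^4`` (equivalent to the double sum
    over ordered pairs)."""
    p = np.asarray(list(p), dtype=float)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2**2 - s4)


@dataclass
class LocusStats:
    """Per-locus diversity bundle."""

    locus_id: str
    N: int
    Na: int
    Ne: float
    I: float
    Ho: float
    He: float
    F: float
    PIC: float

    @property
    def pic_class(self) -> str:
        return classify_pic(self.PIC)

    def as_dict(self) -> dict:
        return {
            "locus_id": self.locus_id, "N": self.N, "Na": self.Na,
            "Ne": self.Ne, "I": self.I, "Ho": self.Ho, "He": self.He,
            "F": self.F, "PIC": self.PIC, "pic_class": self.pic_class,
        }


def locus_stats(
    matrix: GenotypeMatrix, locus_id: str, unbiased_he: bool = False
) -> LocusStats:
    """All Table-style diversity statistics for one locus.

    ``unbiased_he=True`` applies the small-sample correction
    ``2N/(2N-1) * (1 - sum p^2)``; the default is the uncorrected Nei form,
    matching GenAlEx's He column.
    """
    calls = matrix.calls(locus_id)
    ok = (calls != MISSING).all(axis=1)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"locus {locus_id}: all calls missing")
    freqs = allele_frequencies(matrix, locus_id)
    p = np.array(list(freqs.values()))
    s2 = float(np.sum(p**2))
    he = 1.0 - s2
    if unbiased_he:
        he *= 2 * n / (2 * n - 1)
    ho = float(np.mean(calls[ok, 0] != calls[ok, 1]))
    f = (he - ho) / he if he > 0 else 0.0
    return LocusStats(
        locus_id=locus_id,
        N=n,
        Na=len(freqs),
        Ne=1.0 / s2,
        I=float(-np.sum(p * np.log(p))),
        Ho=ho,
        He=he,
        F=f,
        PIC=pic_botstein(p),
    )


def classify_pic(pic: float) -> str:
    """Band a PIC value: low < 0.25 <= moderate < 0.50 <= high."""
    if not 0.0 <= pic <= 1.0:
        raise ValueError("PIC must be in [0,1]")
    if pic < 0.25:
        return "low"
    if pic < 0.50:
        return "moderate"
    return "high"


def panel_summary(
    matrix: GenotypeMatrix, unbiased_he: bool = False
) -> pd.DataFrame:
    """Per-locus stats table plus an unweighted ``Mean`` row.

    The table is indexed by locus id; ``df.attrs["total_na"]`` carries the
    summed allele count across loci.
    """
    rows = [locus_stats(matrix, loc, unbiased_he) for loc in matrix.locus_ids]
    df = pd.DataFrame([r.as_dict() for r in rows]).set_index("locus_id")
    means = df[STAT_COLUMNS].mean()
    df.loc["Mean", STAT_COLUMNS] = means
    df.attrs["total_na"] = int(sum(r.Na for r in rows))
    return df


def column_means(stats: Iterable[LocusStats]) -> dict[str, float]:
    """Unweighted column means over a collection of per-locus stats."""
    df = pd.DataFrame([s.as_dict() for s in stats])
    return {c: float(df[c].mean()) for c in STAT_COLUMNS}


def fixation_index(ho: float, he: float) -> float:
    """``F = (He - Ho)/He`` (0 when He is 0)."""
    return (he - ho) / he if he > 0 else 0.0


def screen_markers(
    stats_table: pd.DataFrame, min_na: int = 3, min_pic: float = 0.30
) -> list[str]:
    """Locus ids with Na >= *min_na* and PIC strictly > *min_pic*; this is
    the reproducible-band / informativeness screen applied to candidate
    markers."""
    df = stats_table.drop(index="Mean", errors="ignore")
    keep = (df["Na"] >= min_na) & (df["PIC"] > min_pic)
    return list(df.index[keep])


def bin_fragment_sizes(matrix: GenotypeMatrix, tolerance: int = 1) -> GenotypeMatrix:
    """Optionally merge allele labels differing by <= *tolerance* bp at each
    locus (fragment-size binning helper; off by default in all pipelines).
    Cluster representatives are the smallest size in each bin."""
    data = matrix.data.copy()
    for j in range(matrix.n_loci):
        sizes = sorted(set(data[:, j, :].ravel()) - {MISSING})
        mapping: dict[int, int] = {}
        rep = prev = None
        for s in sizes:
            if prev is None or s - prev > tolerance:
                rep = s
            mapping[s] = rep
            prev = s
        for s, r in mapping.items():
            data[:, j, :][matrix.data[:, j, :] == s] = r
    return GenotypeMatrix(matrix.accession_ids, matrix.locus_ids, data)
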