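"""Population structure analyses over codominant genotype matrices.

Covers Nei's (1972) standard genetic distance, UPGMA clustering with Newick
output, three-level AMOVA (among populations / among individuals within
populations / within individuals) on an infinite-allele 0/1 allele distance,
AMOVA-based pairwise Fst, per-cluster diversity summaries, and the Evanno
delta-K rule for choosing the number of clusters from replicate model
log-likelihoods (the Bayesian clustering runs themselves are an input, not
reproduced here).

AMOVA follows the classical hierarchical ANOVA on allele copies: with k
populations of N total diploid individuals the degrees of freedom are
(k - 1, N - k, N), the expected mean squares are

    MS_WI = s2_wi
    MS_AI = s2_wi + 2 s2_ai
    MS_AP = s2_wi + 2 s2_ai + 2 n_c s2_ap,   n_c = (N - sum N_p^2 / N)/(k-1)

and negative variance-component estimates are truncated to zero by default
(the GenAlEx convention); raw estimates are kept alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_stats import (
    MISSING,
    GenotypeMatrix,
    allele_frequencies,
    panel_summary,
)

# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.diag(v).any():
            raise ValueError("diagonal must be zero")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_lower_triangle_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                cells = [f"{self.values[i, j]:.3f}" for j in range(i + 1)]
                fh.write(lab + "\t" + "\t".join(cells) + "\n")


FreqSet = Mapping[str, Mapping[int, float]]  # locus -> allele -> frequency


def nei_distance(
    freqs_a: FreqSet, freqs_b: FreqSet, zero_identity: float = math.inf
) -> float:
    """Nei's (1972) standard genetic distance between two allele-frequency
    sets sharing a locus panel:

        D = -ln( J_xy / sqrt(J_x * J_y) )

    with J summed over loci and alleles.  When the normalised identity is 0
    (no shared alleles anywhere) the configured *zero_identity* sentinel is
    returned (default +inf)."""
    if set(freqs_a) != set(freqs_b):
        raise ValueError("locus sets must match")
    jxy = jx = jy = 0.0
    for locus in freqs_a:
        pa, pb = freqs_a[locus], freqs_b[locus]
        jxy += sum(pa.get(al, 0.0) * q for al, q in pb.items())
        jx += sum(p * p for p in pa.values())
        jy += sum(q * q for q in pb.values())
    identity = jxy / math.sqrt(jx * jy)
    if identity <= 0.0:
        return zero_identity
    return max(0.0, -math.log(min(identity, 1.0)))


def group_allele_frequencies(
    matrix: GenotypeMatrix, grouping: Mapping[str, str]
) -> dict[str, dict[str, dict[int, float]]]:
    """Per-population per-locus allele frequencies."""
    out: dict[str, dict[str, dict[int, float]]] = {}
    for pop in dict.fromkeys(grouping.values()):
        ids = [a for a in matrix.accession_ids if grouping[a] == pop]
        sub = matrix.subset_accessions(ids)
        freqs = {}
        for loc in sub.locus_ids:
            try:
                freqs[loc] = allele_frequencies(sub, loc)
            except ValueError:
                pass  # no data for this locus in this group
        out[pop] = freqs
    return out


def nei_distance_matrix(
    matrix: GenotypeMatrix,
    grouping: Mapping[str, str],
    cap: float | None = None,
) -> DistanceMatrix:
    """Pairwise Nei distance between populations (or accessions, when the
    grouping maps each accession to itself).  *cap* replaces infinite
    distances with a finite value for tree building."""
    freqs = group_allele_frequencies(matrix, grouping)
    labels = list(freqs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fa, fb = freqs[labels[i]], freqs[labels[j]]
            common = set(fa) & set(fb)  # loci genotyped in both groups
            if not common:
                raise ValueError(
                    f"no shared genotyped loci between {labels[i]} and {labels[j]}"
                )
            val = nei_distance({l: fa[l] for l in common},
                               {l: fb[l] for l in common})
            if math.isinf(val) and cap is not None:
                val = cap
            d[i, j] = d[j, i] = val
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """UPGMA tree node; ``height`` is the node's distance-from-leaves level,
    so an ultrametric tree has all leaves at height 0."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0
    branch_length: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def _fmt(self, x: float) -> str:
        return f"{x:g}"

    def _newick(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self._fmt(self.branch_length)}"
        inner = ",".join(c._newick() for c in self.children)
        return f"({inner}):{self._fmt(self.branch_length)}"

    def newick(self) -> str:
        if self.is_leaf:
            return f"{self.name};"
        inner = ",".join(c._newick() for c in self.children)
        return f"({inner});"

    def leaf_depths(self) -> dict[str, float]:
        out: dict[str, float] = {}

        def walk(node: TreeNode, depth: float) -> None:
            if node.is_leaf:
                out[node.name] = depth
            for c in node.children:
                walk(c, depth + c.branch_length)

        walk(self, 0.0)
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.leaf_depths().values())
        return max(depths) - min(depths) <= tol


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration of a distance matrix.

    Node height is half the merge distance; ties are broken by the lowest
    (i, j) label-index pair.  Raises on NaN distances.
    """
    d = dist.values.copy()
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least two labels")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=dist.labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    # lowest original label index inside each cluster: drives tie-breaking
    # and child ordering, so the tree is invariant under label permutation
    low = {i: i for i in range(n)}
    active = list(range(n))
    dd = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(active) > 1:
        best = min(
            ((dd[(min(i, j), max(i, j))], i, j)
             for ai, i in enumerate(active) for j in active[ai + 1:]),
            key=lambda t: (t[0], min(low[t[1]], low[t[2]]),
                           max(low[t[1]], low[t[2]])),
        )
        dmin, i, j = best
        if low[j] < low[i]:
            i, j = j, i
        hi, hj = nodes[i], nodes[j]
        height = dmin / 2.0
        hi.branch_length = height - hi.height
        hj.branch_length = height - hj.height
        parent = TreeNode(children=[hi, hj], height=height)
        k = next_id
        next_id += 1
        for m in active:
            if m in (i, j):
                continue
            dim = dd[(min(i, m), max(i, m))]
            djm = dd[(min(j, m), max(j, m))]
            dd[(min(k, m), max(k, m))] = (
                sizes[i] * dim + sizes[j] * djm
            ) / (sizes[i] + sizes[j])
        sizes[k] = sizes[i] + sizes[j]
        low[k] = min(low[i], low[j])
        nodes[k] = parent
        active = [m for m in active if m not in (i, j)] + [k]
    return nodes[active[0]]


# ---------------------------------------------------------------------------
# AMOVA and Fst
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """Three-level AMOVA result."""

    table: pd.DataFrame  # rows: among_populations, among_individuals, within_individuals, total
    sigma_raw: dict[str, float]
    n_c: float

    LEVELS = ("among_populations", "among_individuals", "within_individuals")

    @property
    def percents(self) -> dict[str, float]:
        return {lv: float(self.table.loc[lv, "percent"]) for lv in self.LEVELS}

    @property
    def fst(self) -> float:
        """Proportion of total variance among populations (Phi-ST style)."""
        total = float(self.table.loc["total", "sigma2"])
        if total <= 0:
            return 0.0
        return float(self.table.loc["among_populations", "sigma2"]) / total

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


def _ss_from_counts(counts: np.ndarray, n: int) -> float:
    """SS over a set of *n* allele copies with per-allele counts *counts*:
    sum over unordered pairs of 0/1 distance, divided by n."""
    if n == 0:
        return 0.0
    unequal_pairs = (n * n - float(np.sum(counts**2))) / 2.0
    return unequal_pairs / n


def amova(
    matrix: GenotypeMatrix,
    grouping: Mapping[str, str],
    truncate: bool = True,
) -> VarianceComponents:
    """Three-level AMOVA over all loci (0/1 allele distance, loci summed).

    Requires >= 2 populations each with >= 2 individuals.  Degrees of
    freedom use the full design (k-1, N-k, N) regardless of scattered
    missing calls.
    """
    pops = list(dict.fromkeys(grouping[a] for a in matrix.accession_ids))
    members = {
        p: [a for a in matrix.accession_ids if grouping[a] == p] for p in pops
    }
    k = len(pops)
    if k < 2:
        raise ValueError("need >= 2 populations")
    sizes = {p: len(m) for p, m in members.items()}
    if min(sizes.values()) < 2:
        raise ValueError("every population needs >= 2 individuals")
    N = matrix.n_accessions

    acc_pop = np.array([pops.index(grouping[a]) for a in matrix.accession_ids])
    ss_total = ss_wp = ss_wi = 0.0
    for loc in matrix.locus_ids:
        calls = matrix.calls(loc)
        ok = (calls != MISSING).all(axis=1)
        copies = calls[ok].ravel()
        alleles = np.unique(copies)
        # total
        tot_counts = np.array([np.sum(copies == a) for a in alleles], dtype=float)
        ss_total += _ss_from_counts(tot_counts, len(copies))
        # within populations
        for pi in range(k):
            sel = ok & (acc_pop == pi)
            pc = calls[sel].ravel()
            cnts = np.array([np.sum(pc == a) for a in alleles], dtype=float)
            ss_wp += _ss_from_counts(cnts, len(pc))
        # within individuals: each heterozygous individual contributes 1/2
        het = calls[ok, 0] != calls[ok, 1]
        ss_wi += float(het.sum()) / 2.0
    ss_ap = ss_total - ss_wp
    ss_ai = ss_wp - ss_wi

    df_ap, df_ai, df_wi = k - 1, N - k, N
    ms_ap, ms_ai, ms_wi = ss_ap / df_ap, ss_ai / df_ai, ss_wi / df_wi
    n_c = (N - sum(s * s for s in sizes.values()) / N) / (k - 1)
    sigma_wi = ms_wi
    sigma_ai = (ms_ai - ms_wi) / 2.0
    sigma_ap = (ms_ap - ms_ai) / (2.0 * n_c)
    raw = {
        "among_populations": sigma_ap,
        "among_individuals": sigma_ai,
        "within_individuals": sigma_wi,
    }
    est = {lv: (max(0.0, v) if truncate else v) for lv, v in raw.items()}
    total_sigma = sum(est.values())
    rows = []
    for lv, df, ss, ms in (
        ("among_populations", df_ap, ss_ap, ms_ap),
        ("among_individuals", df_ai, ss_ai, ms_ai),
        ("within_individuals", df_wi, ss_wi, ms_wi),
    ):
        pct = 100.0 * est[lv] / total_sigma if total_sigma > 0 else 0.0
        rows.append(
            {"level": lv, "df": df, "SS": ss, "MS": ms,
             "sigma2": est[lv], "percent": pct}
        )
    rows.append(
        {"level": "total", "df": df_ap + df_ai + df_wi,
         "SS": ss_total, "MS": float("nan"),
         "sigma2": total_sigma, "percent": 100.0 if total_sigma > 0 else 0.0}
    )
    table = pd.DataFrame(rows).set_index("level")
    return VarianceComponents(table=table, sigma_raw=raw, n_c=n_c)


def pairwise_fst(
    matrix: GenotypeMatrix, grouping: Mapping[str, str]
) -> DistanceMatrix:
    """AMOVA-based Fst for every population pair: the among-population
    variance share from the hierarchy restricted to that pair, clipped to
    [0, 1]."""
    pops = list(dict.fromkeys(grouping[a] for a in matrix.accession_ids))
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    n = len(pops)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ids = [a for a in matrix.accession_ids
                   if grouping[a] in (pops[i], pops[j])]
            sub = matrix.subset_accessions(ids)
            vc = amova(sub, {a: grouping[a] for a in ids})
            vals[i, j] = vals[j, i] = float(np.clip(vc.fst, 0.0, 1.0))
    return DistanceMatrix(pops, vals)


def grouped_diversity(
    matrix: GenotypeMatrix, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Per-population diversity means (N, Na, Ne, I, Ho, He, F averaged over
    loci) with an overall ``Mean`` row.  N is the mean per-locus genotyped
    count, hence non-integer."""
    pops = list(dict.fromkeys(grouping[a] for a in matrix.accession_ids))
    rows = []
    for pop in pops:
        ids = [a for a in matrix.accession_ids if grouping[a] == pop]
        if not ids:
            raise ValueError(f"population {pop} is empty")
        sub = matrix.subset_accessions(ids)
        summ = panel_summary(sub)
        means = summ.loc["Mean"]
        rows.append(
            {"population": pop, "N": means["N"], "Na": means["Na"],
             "Ne": means["Ne"], "I": means["I"], "Ho": means["Ho"],
             "He": means["He"], "F": means["F"]}
        )
    df = pd.DataFrame(rows).set_index("population")
    df.loc["Mean"] = df.mean()
    return df


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------


@dataclass
class DeltaKTable:
    table: pd.DataFrame  # index K; columns n_reps, mean_l, sd_l, delta_k
    optimal_k: int | None

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


def evanno_delta_k(runs: Mapping[int, Sequence[float]]) -> DeltaKTable:
    """Evanno's second-difference statistic over replicate log-likelihoods:

        dK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))

    defined for interior K with sd > 0 (sample sd, n-1 denominator); the
    optimal K maximises dK over defined values."""
    ks = sorted(runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(runs[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K")
    mean_l = {k: float(np.mean(runs[k])) for k in ks}
    sd_l = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = float("nan")
        if ks[0] < k < ks[-1] and sd_l[k] > 0:
            dk = abs(mean_l[k + 1] - 2 * mean_l[k] + mean_l[k - 1]) / sd_l[k]
        rows.append({"K": k, "n_reps": len(runs[k]), "mean_l": mean_l[k],
                     "sd_l": sd_l[k], "delta_k": dk})
    df = pd.DataFrame(rows).set_index("K")
    defined = df["delta_k"].dropna()
    optimal = int(defined.idxmax()) if len(defined) else None
    return DeltaKTable(table=df, optimal_k=optimal)
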