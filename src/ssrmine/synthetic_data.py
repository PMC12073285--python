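"""Deterministic generators for every input the pipeline consumes.

Three generators, all driven by one integer seed through numpy's PCG64
generator so outputs are bit-for-bit reproducible:

* :func:`simulate_reference` — scaffolds of SSR-free random background with
  perfect repeat tracts planted at recorded coordinates (the truth table);
* :func:`simulate_population_vcf` — a multi-sample VCF whose ALT alleles are
  repeat-count expansions of the planted tracts, with QUAL/GQ/DP drawn so a
  known subset of sites and calls violates the QC thresholds;
* :func:`simulate_genotype_matrix` — a diploid fragment-size panel drawn
  from subpopulations diverged under the Balding-Nichols model (frequencies
  Dirichlet-perturbed around ancestral ones with E[Fst] equal to the
  divergence parameter), genotypes in Hardy-Weinberg proportions within
  subpopulations.

The study design emulated by the defaults: 60 resequenced accessions feed
the VCF stage, a 149-accession panel with three subpopulations feeds the
genotype stage, and ~20 markers with 3-12 alleles each carry the diversity
analyses.  Fragment-size alleles are encoded as base size + motif length x
(repeat count difference), so allele labels map 1:1 to repeat counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import repeat_miner
from .genotype_stats import GenotypeMatrix
from .repeat_miner import RepeatCriteria, SSRHit
from .variant_pipeline import QCThresholds

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all three generators; the defaults are the study
    conditions (accession counts, three subpopulations, low missingness)."""

    seed: int = 0
    # reference
    n_scaffolds: int = 2
    scaffold_length: int = 8000
    planted_per_scaffold: int = 6
    mono_per_scaffold: int = 1
    compound_pairs_per_scaffold: int = 1
    # VCF
    n_accessions_vcf: int = 60
    qual_fail_fraction: float = 0.2
    gq_fail_rate: float = 0.05
    dp_fail_rate: float = 0.03
    short_indel_fraction: float = 0.2
    # genotype matrix
    n_accessions: int = 149
    n_subpops: int = 3
    divergence: float = 0.08
    n_loci: int = 20
    alleles_range: tuple[int, int] = (3, 8)
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        if self.alleles_range[0] < 2:
            raise ValueError("need >= 2 alleles per locus")


# ---------------------------------------------------------------------------
# Reference scaffolds with planted SSRs
# ---------------------------------------------------------------------------

def _random_primitive_motif(rng: np.random.Generator, k: int) -> str:
    while True:
        m = "".join(rng.choice(BASES, size=k))
        if repeat_miner.is_primitive(m):
            return m


def _clean_background(
    rng: np.random.Generator, length: int, criteria: RepeatCriteria,
    max_iter: int = 200,
) -> np.ndarray:
    """Random sequence rejection-sampled until it contains no SSR meeting
    *criteria* (hit spans are re-randomised until the scan is clean)."""
    seq = rng.choice(BASES, size=length)
    for _ in range(max_iter):
        hits = repeat_miner.find_ssrs("".join(seq), criteria)
        if not hits:
            return seq
        for h in hits:
            seq[h.start - 1 : h.end] = rng.choice(BASES, size=h.length)
    raise RuntimeError("could not generate SSR-free background")


def _plant(seq: np.ndarray, start0: int, motif: str, count: int,
           rng: np.random.Generator) -> None:
    """Write a tract into *seq* (0-based start) and break both flanks so the
    tract cannot extend: the base before must differ from the motif's last
    base, the base after from its first."""
    k = len(motif)
    tract = np.array(list(motif * count))
    seq[start0 : start0 + k * count] = tract
    if start0 > 0 and seq[start0 - 1] == motif[-1]:
        seq[start0 - 1] = rng.choice([b for b in "ACGT" if b != motif[-1]])
    end0 = start0 + k * count - 1
    if end0 + 1 < len(seq) and seq[end0 + 1] == motif[0]:
        seq[end0 + 1] = rng.choice([b for b in "ACGT" if b != motif[0]])


def simulate_reference(
    config: SimulationConfig | None = None,
    criteria: RepeatCriteria | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Scaffolds with planted SSR tracts and their truth table.

    Truth columns: scaffold, start, end (1-based inclusive), motif,
    repeat_count, motif_len, is_mono, compound.  Planted tracts are spaced
    so that only the deliberately compound pairs fall within the compound
    gap; the result is verified against :func:`repeat_miner.find_ssrs` and
    regenerated (new substream) on the rare clash.
    """
    config = config or SimulationConfig()
    criteria = criteria or RepeatCriteria()
    rng = np.random.default_rng(config.seed)
    records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    for s in range(config.n_scaffolds):
        for attempt in range(10):
            rows = _simulate_scaffold(
                rng, f"scaffold_{s + 1}", config, criteria
            )
            if rows is not None:
                records.append(rows[0])
                truth_rows.extend(rows[1])
                break
        else:
            raise RuntimeError("scaffold generation failed repeatedly")
    truth = pd.DataFrame(
        truth_rows,
        columns=["scaffold", "start", "end", "motif", "repeat_count",
                 "motif_len", "is_mono", "compound"],
    )
    return records, truth


def _simulate_scaffold(rng, name, config, criteria):
    n_main = config.planted_per_scaffold
    length = config.scaffold_length
    seq = _clean_background(rng, length, criteria)
    slot = length // max(n_main, 1)
    if slot < 400:
        raise ValueError("scaffold too short for the requested plant count")
    rows = []
    n_mono = config.mono_per_scaffold
    n_compound = config.compound_pairs_per_scaffold
    for i in range(n_main):
        if i < n_mono:
            k = 1
            motif = str(rng.choice(BASES))
        else:
            k = int(rng.integers(2, 5))  # di / tri / tetra
            motif = _random_primitive_motif(rng, k)
        count = int(criteria.min_repeats[k] + rng.integers(0, 5))
        start0 = i * slot + int(rng.integers(160, slot - 160 - k * count))
        _plant(seq, start0, motif, count, rng)
        is_compound_pair = n_mono <= i < n_mono + n_compound
        rows.append({
            "scaffold": name, "start": start0 + 1,
            "end": start0 + k * count, "motif": motif,
            "repeat_count": count, "motif_len": k,
            "is_mono": k == 1, "compound": is_compound_pair,
        })
        if is_compound_pair:
            k2 = int(rng.integers(2, 5))
            motif2 = _random_primitive_motif(rng, k2)
            count2 = int(criteria.min_repeats[k2] + rng.integers(0, 5))
            gap = int(rng.integers(20, 80))
            start2 = start0 + k * count + gap
            _plant(seq, start2, motif2, count2, rng)
            rows.append({
                "scaffold": name, "start": start2 + 1,
                "end": start2 + k2 * count2, "motif": motif2,
                "repeat_count": count2, "motif_len": k2,
                "is_mono": False, "compound": True,
            })
    text = "".join(seq)
    found = repeat_miner.find_ssrs(text, criteria, seq_id=name)
    expect = sorted((r["start"], r["end"], r["motif"]) for r in rows)
    got = sorted((h.start, h.end, h.motif) for h in found)
    if expect != got:
        return None  # rare background/plant interaction; caller retries
    return (name, text), rows


def write_fasta(records: Sequence[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Population VCF
# ---------------------------------------------------------------------------

def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, fst: float
) -> np.ndarray:
    """Subpopulation frequencies with E[Fst] = *fst* around ancestral *p*."""
    if fst <= 0:
        return p.copy()
    alpha = p * (1.0 - fst) / fst
    # Dirichlet needs strictly positive concentration
    return rng.dirichlet(np.maximum(alpha, 1e-6))


def simulate_population_vcf(
    reference: Sequence[tuple[str, str]],
    ref_truth: pd.DataFrame,
    config: SimulationConfig | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[str, pd.DataFrame]:
    """VCF text (4.2, GT:GQ:DP) plus a per-site truth table.

    Every planted tract yields one site anchored one base before the tract:
    REF is anchor + tract, ALTs are repeat-count expansions.  A configured
    fraction of sites gets only short (<= 10 bp) length changes, QUAL below
    threshold, or enough failing calls to breach the missing-rate rule; the
    truth table records, from the planted values alone, how each QC rule
    should judge the site.
    """
    config = config or SimulationConfig()
    thr = thresholds or QCThresholds()
    rng = np.random.default_rng(config.seed + 1)
    ref = dict(reference)
    n = config.n_accessions_vcf
    samples = [f"S{i + 1:03d}" for i in range(n)]
    subpop = np.array([i * config.n_subpops // n for i in range(n)])

    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for name, seq in reference:
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))

    truth_rows = []
    for row in ref_truth.itertuples(index=False):
        seq = ref[row.scaffold]
        k = row.motif_len
        count = row.repeat_count
        pos = row.start - 1  # anchor base position, 1-based
        if pos < 1:
            continue
        anchor = seq[pos - 1]
        tract = row.motif * count
        ref_allele = anchor + tract

        # compound-pair members always get a long allele so that locus-level
        # compound flagging (which needs both neighbours in the VCF) stays
        # predictable from the truth table
        is_short = (not row.compound) and rng.random() < config.short_indel_fraction
        if is_short:
            delta = max(1, 10 // k)  # length change <= 10
        else:
            delta = int(np.ceil(11 / k)) + int(rng.integers(0, 3))
        alts = [anchor + row.motif * (count + delta)]
        if rng.random() < 0.3:  # occasional second expansion allele
            alts.append(anchor + row.motif * (count + delta + 1))
        max_diff = max(abs(len(a) - len(ref_allele)) for a in alts)

        qual_fail = rng.random() < config.qual_fail_fraction
        qual = float(rng.uniform(5, 39)) if qual_fail else float(rng.uniform(60, 200))

        n_all = 1 + len(alts)
        anc = rng.dirichlet(np.full(n_all, 2.0))
        pop_freqs = [
            _balding_nichols(rng, anc, config.divergence)
            for _ in range(config.n_subpops)
        ]
        gts, gqs, dps = [], [], []
        n_fail = 0
        for i in range(n):
            f = pop_freqs[subpop[i]]
            a, b = rng.choice(n_all, size=2, p=f)
            gq_fail = rng.random() < config.gq_fail_rate
            dp_fail = rng.random() < config.dp_fail_rate
            gq = int(rng.integers(5, 40)) if gq_fail else int(rng.integers(60, 99))
            dp = (int(rng.choice([1, 2, 3, 4, 110, 140]))
                  if dp_fail else int(rng.integers(10, 80)))
            if gq_fail or dp_fail:
                n_fail += 1
            gts.append((int(a), int(b)))
            gqs.append(gq)
            dps.append(dp)

        # truth-side QC verdict from planted values (call masked iff its
        # GQ <= min_gq or DP outside dp_range)
        masked = [
            not (g > thr.min_gq and thr.dp_range[0] <= d <= thr.dp_range[1])
            for g, d in zip(gqs, dps)
        ]
        kept = [gt for gt, m in zip(gts, masked) if not m]
        counts: dict[int, int] = {}
        for a, b in kept:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        tot = sum(counts.values())
        if tot and len(counts) > 1:
            maf = sorted(counts.values(), reverse=True)[1] / tot
        else:
            maf = 0.0
        miss = (n - len(kept)) / n
        maf_ok = maf < thr.maf_bound if thr.maf_mode == "lt" else maf >= thr.maf_bound
        qc_pass = qual > thr.min_qual and (maf_ok or miss <= thr.max_missing_rate)

        fields = [
            row.scaffold, str(pos), ".", ref_allele, ",".join(alts),
            f"{qual:.1f}", "PASS", ".", "GT:GQ:DP",
        ]
        for (a, b), gq, dp in zip(gts, gqs, dps):
            fields.append(f"{a}/{b}:{gq}:{dp}")
        lines.append("\t".join(fields))
        truth_rows.append({
            "chrom": row.scaffold, "pos": pos, "motif": row.motif,
            "motif_len": k, "repeat_count": count,
            "max_len_diff": max_diff, "is_long": max_diff > 10,
            "qual": qual, "qual_pass": qual > thr.min_qual,
            "n_masked_calls": sum(masked), "missing_rate": miss,
            "maf": maf, "qc_pass": qc_pass,
            "is_mono": row.is_mono, "compound": bool(row.compound),
        })
    truth = pd.DataFrame(truth_rows)
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTruth:
    assignments: dict[str, str]          # accession -> subpopulation
    ancestral: dict[str, np.ndarray]     # locus -> ancestral frequencies
    subpop_freqs: dict[str, dict[str, np.ndarray]]  # pop -> locus -> freqs
    allele_sizes: dict[str, np.ndarray]  # locus -> fragment sizes (bp)


def simulate_genotype_matrix(
    config: SimulationConfig | None = None,
) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """Diploid fragment-size panel drawn from Balding-Nichols
    subpopulations under within-subpopulation Hardy-Weinberg equilibrium."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed + 2)
    n, n_pops = config.n_accessions, config.n_subpops
    acc_ids = [f"CX{i + 1:03d}" for i in range(n)]
    pops = [f"pop{j + 1}" for j in range(n_pops)]
    assignment = {acc_ids[i]: pops[i * n_pops // n] for i in range(n)}

    locus_ids = [f"SSR{j + 1:02d}" for j in range(config.n_loci)]
    ancestral: dict[str, np.ndarray] = {}
    subpop_freqs: dict[str, dict[str, np.ndarray]] = {p: {} for p in pops}
    allele_sizes: dict[str, np.ndarray] = {}
    data = np.zeros((n, config.n_loci, 2), dtype=np.int64)
    for j, loc in enumerate(locus_ids):
        na = int(rng.integers(config.alleles_range[0],
                              config.alleles_range[1] + 1))
        anc = rng.dirichlet(np.full(na, 2.0))
        motif_len = int(rng.choice([2, 3]))
        base = int(rng.integers(120, 260))
        sizes = base + motif_len * np.arange(na)
        ancestral[loc] = anc
        allele_sizes[loc] = sizes
        for p in pops:
            subpop_freqs[p][loc] = _balding_nichols(rng, anc, config.divergence)
        for i, acc in enumerate(acc_ids):
            f = subpop_freqs[assignment[acc]][loc]
            a, b = rng.choice(na, size=2, p=f)
            data[i, j] = (sizes[a], sizes[b])
    if config.missing_rate > 0:
        mask = rng.random((n, config.n_loci)) < config.missing_rate
        data[mask] = 0
    matrix = GenotypeMatrix(acc_ids, locus_ids, data)
    truth = GenotypeTruth(assignment, ancestral, subpop_freqs, allele_sizes)
    return matrix, truth


def write_grouping_tsv(assignments: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tpopulation\n")
        for acc, pop in assignments.items():
            fh.write(f"{acc}\t{pop}\n")


def read_grouping_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def simulate_delta_k_table(
    rng: np.random.Generator,
    planted_k: int = 3,
    k_range: tuple[int, int] = (1, 8),
    n_reps: int = 10,
    knee: float = 400.0,
    noise: float = 5.0,
) -> dict[int, list[float]]:
    """Replicate log-likelihood tables with a planted knee: mean L(K) rises
    steeply up to *planted_k* then flattens, so the second difference (and
    hence delta-K) peaks at the planted K."""
    lo, hi = k_range
    means = {}
    level = -5000.0
    for k in range(lo, hi + 1):
        gain = knee if k <= planted_k else knee * 0.05
        level += gain
        means[k] = level
    return {
        k: list(means[k] + rng.normal(0.0, noise, size=n_reps))
        for k in range(lo, hi + 1)
    }
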