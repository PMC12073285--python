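"""Population-VCF stage: long-InDel extraction, QC, SSR locus collapsing and
candidate selection.

The marker-discovery route implemented here mines microsatellites not from a
reference assembly but from the InDel alleles segregating in a resequenced
population: an SSR whose repeat count varies between accessions shows up as a
long insertion/deletion in the population VCF, so filtering the VCF to long
InDels and scanning the allele sequences for tandem repeats yields exactly
the polymorphic subset of the genome's SSRs.

QC mirrors common practice for resequencing panels: site QUAL > 40,
individual calls masked unless GQ > 40 and 5 <= DP <= 100, then a site-level
rule on minor allele frequency / missingness.  The MAF arm is applied as a
literal disjunction ``MAF < bound OR F_MISSING <= bound`` under
``maf_mode="lt"``; because a keep-if-rare rule is unusual, the conventional
``maf_mode="ge"`` (keep common variants) is provided as well.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from . import repeat_miner
from ._util import DNA_BASES_N
from .repeat_miner import RepeatCriteria, SSRHit

log = logging.getLogger(__name__)

#: length difference (bp) an InDel must exceed to be SSR-informative
LONG_INDEL_MIN_DIFF = 10

MISSING_CALL = (-1, -1)


@dataclass
class VariantRecord:
    """One VCF site with the per-sample fields the pipeline needs."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    genotypes: list[tuple[int, int]]  # allele indices, (-1,-1) = missing
    gq: np.ndarray | None = None  # per-sample genotype quality
    dp: np.ndarray | None = None  # per-sample depth

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)


@dataclass(frozen=True)
class QCThresholds:
    """Site/call-level QC rules.

    ``maf_mode="lt"`` keeps sites with MAF < ``maf_bound`` (prioritising
    low-frequency variants) OR missing rate <= ``max_missing_rate``;
    ``"ge"`` flips the MAF arm to the conventional keep-common rule.
    """

    min_qual: float = 40.0
    min_gq: float = 40.0
    dp_range: tuple[int, int] = (5, 100)
    maf_bound: float = 0.05
    max_missing_rate: float = 0.05
    maf_mode: str = "lt"

    def __post_init__(self) -> None:
        if self.dp_range[0] > self.dp_range[1]:
            raise ValueError("dp_range low must be <= high")
        for r in (self.maf_bound, self.max_missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0,1]")
        if self.maf_mode not in ("lt", "ge"):
            raise ValueError("maf_mode must be 'lt' or 'ge'")


@dataclass
class SSRLocus:
    """A collapsed SSR locus keyed by genomic position."""

    locus_id: str
    chrom: str
    pos: int
    motif: str
    n_supporting_sequences: int
    mononucleotide: bool = False
    compound: bool = False
    qc_pass: bool = True
    has_secondary_genotype: bool = False

    @property
    def canonical_label(self) -> str:
        return repeat_miner.canonical_motif(self.motif)


@dataclass
class GenotypeFrequencySummary:
    """Ranked (non-increasing) genotype frequencies at one locus."""

    locus_id: str
    ranked: tuple[float, ...]
    n_genotyped: int
    genotype_counts: dict[tuple, int] = field(default_factory=dict)

    @property
    def secondary(self) -> float:
        return self.ranked[1] if len(self.ranked) > 1 else 0.0


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_vcf(path) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF 4.x file (plain or gzipped)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    for v in vcf:
        gts = []
        for g in v.genotypes:
            a, b = g[0], g[1] if len(g) > 2 else g[0]
            gts.append((a, b) if a >= 0 and b >= 0 else MISSING_CALL)
        gq = v.format("GQ")
        dp = v.format("DP")
        yield VariantRecord(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alts=tuple(v.ALT),
            qual=v.QUAL,
            genotypes=gts,
            gq=None if gq is None else np.asarray(gq, dtype=float).reshape(-1),
            dp=None if dp is None else np.asarray(dp, dtype=float).reshape(-1),
        )


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def _valid_allele(a: str) -> bool:
    return bool(a) and not set(a.upper()) - DNA_BASES_N


def extract_long_indels(
    records: Iterable[VariantRecord],
    min_len_diff: int = LONG_INDEL_MIN_DIFF,
) -> Iterator[VariantRecord]:
    """Keep sites where at least one ALT differs from REF by more than
    *min_len_diff* bp; SNPs, short InDels and malformed records are dropped
    (malformed ones with a warning)."""
    n_skipped = 0
    for rec in records:
        if not _valid_allele(rec.ref) or not all(_valid_allele(a) for a in rec.alts):
            n_skipped += 1
            log.warning("skipping malformed alleles at %s:%d", rec.chrom, rec.pos)
            continue
        if any(abs(len(a) - len(rec.ref)) > min_len_diff for a in rec.alts):
            yield rec
    if n_skipped:
        log.info("extract_long_indels: skipped %d malformed records", n_skipped)


def _mask_calls(rec: VariantRecord, thr: QCThresholds) -> VariantRecord:
    """Return a copy of *rec* with calls failing GQ/DP set to missing."""
    gts = list(rec.genotypes)
    n = len(gts)
    gq = rec.gq
    dp = rec.dp
    if gq is None or dp is None:
        warnings.warn(
            f"missing GQ/DP fields at {rec.chrom}:{rec.pos}; "
            "calls without them are treated as missing",
            stacklevel=3,
        )
    for i in range(n):
        ok = True
        if gq is None or not np.isfinite(gq[i]) or gq[i] <= thr.min_gq:
            ok = False
        if dp is None or not np.isfinite(dp[i]) or not (
            thr.dp_range[0] <= dp[i] <= thr.dp_range[1]
        ):
            ok = False
        if not ok:
            gts[i] = MISSING_CALL
    return replace(rec, genotypes=gts)


def site_maf(rec: VariantRecord) -> float:
    """Minor allele frequency over non-missing calls (second most frequent
    allele; 0.0 when monomorphic or all calls missing)."""
    counts = Counter()
    for a, b in rec.genotypes:
        if (a, b) != MISSING_CALL:
            counts[a] += 1
            counts[b] += 1
    total = sum(counts.values())
    if total == 0 or len(counts) < 2:
        return 0.0
    return sorted(counts.values(), reverse=True)[1] / total


def site_missing_rate(rec: VariantRecord) -> float:
    if rec.n_samples == 0:
        return 1.0
    miss = sum(1 for g in rec.genotypes if g == MISSING_CALL)
    return miss / rec.n_samples


def apply_qc(
    records: Iterable[VariantRecord], thresholds: QCThresholds | None = None
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply call-level masking then site-level QC.

    A site passes iff QUAL > min_qual AND (the MAF arm holds OR the missing
    rate after masking is <= max_missing_rate).  Returns passing records
    (with failing calls masked) and a per-rule rejection tally.
    """
    thr = thresholds or QCThresholds()
    passed: list[VariantRecord] = []
    tally = {"qual": 0, "maf_or_missing": 0}
    for rec in records:
        if rec.qual is None or not rec.qual > thr.min_qual:
            tally["qual"] += 1
            continue
        masked = _mask_calls(rec, thr)
        maf = site_maf(masked)
        miss = site_missing_rate(masked)
        maf_ok = maf < thr.maf_bound if thr.maf_mode == "lt" else maf >= thr.maf_bound
        if maf_ok or miss <= thr.max_missing_rate:
            passed.append(masked)
        else:
            tally["maf_or_missing"] += 1
    return passed, tally


@dataclass(frozen=True)
class LocusCandidate:
    """One SSR hit inside one allele of one VCF site."""

    chrom: str
    pos: int
    hit: SSRHit


def mine_variant_ssrs(
    records: Iterable[VariantRecord], criteria: RepeatCriteria | None = None
) -> list[LocusCandidate]:
    """Scan the longer allele of every long-InDel ALT for SSR tracts.

    Each qualifying hit becomes a locus candidate anchored at the source
    site's (chrom, pos); multiple alleles at one site may each contribute.
    """
    criteria = criteria or RepeatCriteria()
    out: list[LocusCandidate] = []
    for rec in records:
        seen: set[tuple] = set()
        for alt in rec.alts:
            if abs(len(alt) - len(rec.ref)) <= LONG_INDEL_MIN_DIFF:
                continue
            allele = alt if len(alt) > len(rec.ref) else rec.ref
            key0 = allele
            if key0 in seen:  # identical allele sequence scanned once
                continue
            seen.add(key0)
            for hit in repeat_miner.find_ssrs(
                allele, criteria, seq_id=f"{rec.chrom}_{rec.pos}"
            ):
                out.append(LocusCandidate(rec.chrom, rec.pos, hit))
    return out


def collapse_to_loci(candidates: Sequence[LocusCandidate]) -> list[SSRLocus]:
    """Collapse candidates sharing a genomic key to one locus per (chrom, pos).

    The locus motif is the majority motif among its candidates (conflicts are
    logged); ``n_supporting_sequences`` counts the collapsed candidates.
    """
    grouped: dict[tuple[str, int], list[LocusCandidate]] = {}
    order: list[tuple[str, int]] = []
    for c in candidates:
        key = (c.chrom, c.pos)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(c)
    loci = []
    for chrom, pos in order:
        group = grouped[(chrom, pos)]
        motifs = Counter(c.hit.motif for c in group)
        if len(motifs) > 1:
            log.warning(
                "conflicting motifs at %s:%d: %s; keeping majority",
                chrom, pos, dict(motifs),
            )
        motif = motifs.most_common(1)[0][0]
        loci.append(
            SSRLocus(
                locus_id=f"{chrom}_{pos}",
                chrom=chrom,
                pos=pos,
                motif=motif,
                n_supporting_sequences=len(group),
                mononucleotide=len(motif) == 1,
                compound=any(c.hit.compound for c in group),
            )
        )
    return loci


def filter_locus_classes(
    loci: Sequence[SSRLocus], max_compound_gap: int = 100
) -> list[SSRLocus]:
    """Drop mononucleotide loci and compound loci.

    A locus is compound if its own allele carried multiple nearby tracts or
    if another locus on the same chromosome lies within *max_compound_gap*
    bp. Order is preserved.
    """
    loci = list(loci)
    by_chrom: dict[str, list[SSRLocus]] = {}
    for lc in loci:
        by_chrom.setdefault(lc.chrom, []).append(lc)
    compound_ids = {lc.locus_id for lc in loci if lc.compound}
    for chrom_loci in by_chrom.values():
        chrom_loci.sort(key=lambda l: l.pos)
        for a, b in zip(chrom_loci, chrom_loci[1:]):
            if b.pos - a.pos <= max_compound_gap:
                compound_ids.add(a.locus_id)
                compound_ids.add(b.locus_id)
    out = []
    for lc in loci:
        lc.compound = lc.locus_id in compound_ids
        if not lc.mononucleotide and not lc.compound:
            out.append(lc)
    return out


def genotype_frequencies(matrix, locus_id: str) -> GenotypeFrequencySummary:
    """Ranked unordered-genotype frequencies at one locus of a
    :class:`~ssrmine.genotype_stats.GenotypeMatrix`."""
    calls = matrix.calls(locus_id)
    counts: Counter = Counter()
    for a, b in calls:
        if a and b:  # 0 is the missing sentinel
            counts[tuple(sorted((int(a), int(b))))] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"locus {locus_id}: all calls missing")
    ranked = tuple(sorted((c / n for c in counts.values()), reverse=True))
    return GenotypeFrequencySummary(locus_id, ranked, n, dict(counts))


def select_candidates(
    loci: Sequence[SSRLocus],
    summaries: Mapping[str, GenotypeFrequencySummary],
    min_secondary: float = 0.05,
) -> list[SSRLocus]:
    """Keep loci that possess a secondary common genotype: the second-ranked
    genotype frequency must reach *min_secondary*."""
    out = []
    for lc in loci:
        summ = summaries[lc.locus_id]
        lc.has_secondary_genotype = summ.secondary >= min_secondary
        if lc.has_secondary_genotype:
            out.append(lc)
    return out
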