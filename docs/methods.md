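# Methods

`ssrmine` implements, as a reusable toolkit, the workflow for developing
and evaluating SSR (microsatellite) markers from whole-genome resequencing
data, with the *Aquilaria sinensis* germplasm setting as its motivating
case: repeat mining from population-VCF InDel alleles, locus QC and
candidate selection, primer design, codominant diversity statistics,
population-structure analyses, and germplasm fingerprinting. This note documents the models, conventions and numerical
choices behind each stage, what the synthetic-data generators emulate, and
the known limitations.

## Repeat detection

A perfect SSR tract of period *k* (motif length 1–6) is a maximal run of
positions where `s[i] == s[i+k]`. A run is reported when it contains at
least the class minimum of complete motif copies — 10 for mononucleotide
motifs, 6 for dinucleotide, 5 for tri- through hexanucleotide (the
MISA-style convention this workflow standardises on) — and its motif is
*primitive* (not itself a tandem repetition of a shorter motif). Primitivity
is what makes the shortest-motif explanation win: the period-4 reading of
(AT)₆ has motif ATAT and is rejected. Coordinates are 1-based inclusive,
matching VCF convention. `N` never participates in a repeat, so an `N`
breaks a tract (the conservative repeat-finder convention). Overlapping
tracts with different motifs are both reported; adjacency is handled by the
compound flag: any two tracts separated by ≤ 100 bp (configurable) are
flagged compound, and compound loci are excluded from marker design.

Motif accounting pairs each motif with its reverse complement
(`TAT/ATA`), because a repeat read from the opposite strand is the same
locus; rotations remain distinct labels (AT/AT and TA/TA are counted
separately), which matches how such inventories are conventionally
reported. An optional collapse mode merges a motif and its reverse
complement under the lexicographically smaller member for programmatic
grouping. Class shares and within-class motif shares are reported to 2 dp.

The scanner is verified against an independent brute-force oracle that
tests every (start, motif-length, copy-count) triple exhaustively; the two
agree exactly on randomized kilobase sequences with spliced-in repeats.

## Variant pipeline

Polymorphic SSRs appear in a population VCF as long InDels whose alleles
differ by whole motif copies. The pipeline:

1. **Long-InDel extraction** keeps sites where some ALT differs from REF by
   *more than* 10 bp (strict inequality).
2. **QC** masks individual calls unless GQ > 40 and 5 ≤ DP ≤ 100 (QUAL and
   GQ strict, DP bounds inclusive — "between" read inclusively), then keeps
   a site iff QUAL > 40 and (`MAF < 0.05` **or** missing rate ≤ 0.05).
   The MAF arm is deliberately a keep-if-rare disjunct under the default
   `maf_mode="lt"`; because that rule is unusual, the conventional
   keep-if-common arm is available as `maf_mode="ge"`. MAF is the frequency
   of the second-most-common allele over unmasked calls. Rejections are
   tallied per rule, and tallies + survivors always equal the input.
3. **Mining** runs the repeat scanner over the longer allele of each
   qualifying ALT; each hit becomes a locus candidate anchored at the
   source site's (chrom, pos). The repeat's offset inside the allele is
   *not* added to the locus key, so locus ids take the `{chrom}_{pos}`
   form used in marker tables.
4. **Collapsing** merges candidates per (chrom, pos); the majority motif
   wins on conflicts (logged), and the number of collapsed candidates is
   retained as support.
5. **Class filters** drop mononucleotide loci and compound loci (a locus is
   compound if its own allele carried multiple nearby tracts or another
   locus sits within 100 bp on the same chromosome).
6. **Candidate selection** keeps loci with a *secondary common genotype*:
   the second-ranked genotype frequency must reach `min_secondary`
   (default 0.05; the workflow's reported secondary-genotype frequencies
   bottom out at 0.08, so 0.05 is a permissive floor).

Whether QC precedes or follows mining is configurable (`--order`); the
default is mine-then-QC. VCF input goes through cyvcf2; records with
symbolic or malformed alleles are skipped with a logged warning.

## Primer design

Templates are the tract ± 150 bp (truncated at scaffold ends). Candidate
primers are all windows of 18–27 nt (optimum 20) lying wholly in a flank,
with GC 20–80 % and nearest-neighbour Tm in [57, 61] °C (optimum 60);
pairs must differ by ≤ 5 °C and bracket the full tract with a product of
100–300 bp. Pairs are ranked by a documented penalty — 1 point per nt from
the optimal length, 1 per °C from the optimal Tm, 0.25 per GC% from 50 %,
0.01 per bp from the product-range midpoint, summed over both primers —
and the top 3 per locus are kept (ranked-list semantics; enumeration is
deterministic). A separate post-filter mirrors manual primer screening:
products below the 100 bp floor, any mononucleotide run of ≥ 4 inside a
primer, or primer GC outside 40–60 % ("extreme GC"; deliberately stricter
than the design window so the filter is non-vacuous) are rejected, with a
per-rule tally. An optional stricter mode also rejects ≥ 3 tandem copies
of a dinucleotide motif.

Melting temperatures are computed from self-implemented nearest-neighbour
thermodynamics (SantaLucia 1998 unified ΔH/ΔS table; duplex initiation
terms per terminal base; entropy salt correction 0.368·(n−1)·ln[Na⁺] with
50 mM monovalent; strand concentration 25 nM primer / 25 nM partner, so
CT = 12.5 nM). The Wallace rule 2(A+T) + 4(G+C) is available as a fallback
mode. Tests cross-check the nearest-neighbour mode against Biopython's
independent implementation (agreement within 1 °C on fixed primers);
Biopython is never the runtime path. Dimer/hairpin thermodynamics and
in-silico PCR are out of scope.

## Diversity statistics

The genotype container is an accessions × loci matrix of unordered diploid
fragment-size pairs (integer bp; 0 = missing; half-missing calls count as
missing). Allele labels are exact sizes — no binning by default, though a
±1 bp binning helper exists. Missing calls are excluded locus-wise
(pairwise deletion), so per-locus N varies.

Per locus, with allele frequencies *pᵢ* over 2N genes:

* Na = number of distinct alleles; Ne = 1/Σpᵢ² (effective alleles);
* I = −Σpᵢ ln pᵢ (Shannon);
* Ho = fraction of heterozygous accessions;
* He = 1 − Σpᵢ² (Nei gene diversity; the uncorrected form, matching the
  GenAlEx "He" column — a 2N/(2N−1) unbiased variant is behind a flag);
* F = (He − Ho)/He, defined as 0 when He = 0;
* PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ² (Botstein form, the quantity Cervus
  reports), computed as 1 − S₂ − (S₂² − S₄).

PIC bands: low < 0.25 ≤ moderate < 0.50 ≤ high. The marker screen keeps
loci with Na ≥ 3 and PIC strictly > 0.30. Panel summaries use unweighted
means over loci. Invariants checked by tests: 1 ≤ Ne ≤ Na (equality iff
equifrequent), PIC ≤ He, and Ho → He (so F → 0) as N grows under
Hardy-Weinberg sampling.

## Population structure

**Nei's (1972) standard distance.** D = −ln(J_xy / √(J_x·J_y)) with the
identities summed over loci and alleles. Zero identity (no shared alleles)
is reported as +∞ by default, with an optional finite cap for tree
building. Pairwise distances between groups with scattered missing data
are computed over the loci genotyped in both groups.

**UPGMA.** Self-implemented average-linkage agglomeration: node height is
half the merge distance, ties are broken by the lowest pair of original
label indices, and children are ordered by lowest contained label index —
so output is deterministic and invariant under label permutation. Newick
with branch lengths is emitted; trees are ultrametric by construction.
Tests cross-check cophenetic distances against scipy's average linkage.

**AMOVA.** Three levels — among populations / among individuals within
populations / within individuals — on allele copies with the 0/1
(infinite-allele) distance, loci summed. With k populations and N diploids,
df = (k−1, N−k, N); the expected-mean-square solution uses the
unequal-size coefficient n_c = (N − ΣN_p²/N)/(k−1):

    σ²_within     = MS_WI
    σ²_among_ind  = (MS_AI − MS_WI)/2
    σ²_among_pop  = (MS_AP − MS_AI)/(2·n_c)

Negative estimates are truncated to 0 by default (GenAlEx behaviour); raw
values are preserved alongside. Percentages are σ²/Σσ² on the truncated
estimates and sum to 100 before rounding. Degrees of freedom always use
the full design even when scattered missing calls make per-locus sample
sizes vary — the pragmatic GenAlEx-like choice; simulations with
missingness 0 confirm exactness. Standard level names are used throughout
(published AMOVA tables occasionally swap the two middle row labels; the
mapping here is by df: k−1 / N−k / N).

**Pairwise Fst.** For each population pair the same hierarchy is fitted on
the pair's subset and Fst = σ²_among_pop / σ²_total, clipped to [0, 1] —
the AMOVA/GenAlEx route rather than Weir–Cockerham θ (the estimator name
is recorded in output metadata; numeric agreement with other estimators is
not guaranteed). Under Balding–Nichols simulations the estimator recovers
the divergence parameter (±0.03 at 0.10 with 50 loci, 200 diploids per
population) and is monotone in it.

**Evanno ΔK.** The Bayesian clustering runs themselves are an input (this
package does not implement admixture MCMC). Given replicate log-likelihoods
per K over ≥ 3 consecutive K values:

    ΔK = |mean L(K+1) − 2·mean L(K) + mean L(K−1)| / sd(L(K))

with the sample (n−1) standard deviation. ΔK is undefined at boundary K and
wherever sd = 0 (flagged, excluded from the argmax); the optimal K
maximises ΔK over defined values.

## Fingerprinting

Each (locus, allele) pair becomes a 0/1 column; an accession scores 1 for
every allele it carries. A missing call leaves the locus block zero and is
tracked in a mask. Discrimination groups accessions by identical profiles;
the default `strict` mode makes missingness part of the profile (profiles
are compared as printed), while `ignore` lets missing calls wildcard-match
(groups become connected components of the compatibility graph, which is
non-transitive — hence the graph construction). The discrimination rate is
100 × (accessions in singleton groups)/n, to 2 dp; a group of g
indistinguishable accessions contributes all g members to the ambiguous
count (149 accessions with three duplicate pairs → 143/149 = 95.97 %).

## Synthetic data

All generators run off one integer seed through numpy's PCG64, so outputs
are bit-for-bit reproducible. Defaults mirror the emulated study design:
60 resequenced accessions feeding the VCF stage, a 149-accession panel in
three subpopulations for the genotype analyses, ~20 loci with 3–8 alleles,
2 % missing calls, and a Balding–Nichols divergence of 0.08 (inside the
low-differentiation range the workflow reports).

* **Reference**: scaffolds of random background rejection-sampled until
  repeat-free, with tracts planted at recorded coordinates. Flanking bases
  are chosen to break the tract's period so planted coordinates are exact;
  the result is verified against the scanner and regenerated on the rare
  clash. Deliberate mononucleotide plants and compound pairs (20–80 bp
  apart) exercise the class filters.
* **Population VCF**: one site per planted tract, anchored one base before
  it; ALTs are repeat-count expansions. A configured fraction of sites
  gets only ≤ 10 bp length changes (to test the long-InDel rule), QUAL
  below 40, or enough GQ/DP-failing calls to breach the missing-rate rule.
  Compound-pair members always receive long alleles so locus-level
  compound flagging, which needs both neighbours present, stays
  predictable from the truth table. The truth table records each site's
  expected QC verdict from the planted values alone.
* **Genotype matrix**: ancestral allele frequencies are Dirichlet(2,…,2);
  subpopulation frequencies follow the Balding–Nichols model
  (Dirichlet with concentration p·(1−F)/F, giving E[Fst] = F); genotypes
  are drawn in Hardy-Weinberg proportions within subpopulations. Fragment
  sizes are base + motif-length × allele-index, so allele labels map 1:1
  to repeat counts.

What the generators do **not** emulate: read-level sequencing error,
stepwise-mutation dynamics, null alleles, linkage, admixed individuals, or
genotyping artifacts (stutter, allele dropout). Passing tests therefore
demonstrate correctness of the statistical machinery and filter logic
under the stated models, not robustness to those real-data pathologies.

## Problem sizes and determinism

Test and acceptance runs use deliberately small inputs chosen to finish in
seconds while keeping the estimators in their working range: 2 × 8 kb
scaffolds with 14 planted tracts, 60-sample VCFs, panels of 149–500
accessions, 10–50 loci, N = 2000 only for the Hardy-Weinberg convergence
check, and 100 replicates for the oracle-agreement and ΔK-recovery
properties. Every stochastic step takes an explicit seed; fixed seeds make
the whole suite reproducible bit-for-bit.

## Known limitations

* Variant calling, phasing and multi-allelic normalisation beyond ALT
  splitting are upstream concerns, out of scope.
* The AMOVA df convention under missing data (full-design df) differs from
  tools that recompute df per locus; with ≤ 5 % missingness the effect on
  variance shares is negligible but not zero.
* Fst here is the AMOVA variance-share estimator; it tracks, but does not
  equal, Weir–Cockerham θ or Nei's G_st, especially at high diversity.
* The fingerprint `ignore` mode's connected-component grouping can chain
  accessions that are pairwise compatible only through intermediates; the
  strict mode has no such ambiguity and is the default.
* Genome-scale performance tuning is a non-goal: scans are linear and the
  UPGMA implementation is O(n³), comfortable for hundreds of accessions.
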