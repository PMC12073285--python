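# ssrmine

SSR (microsatellite) marker development and evaluation from whole-genome
resequencing data, packaged as a library + CLI for plant germplasm work.

Large cultivated collections — the motivating case is *Aquilaria sinensis*,
the agarwood tree, whose plantations mix accessions of unclear origin —
need cheap codominant markers to tell accessions apart and to describe
their genetic structure. Because an SSR whose repeat count varies between
individuals surfaces as a long insertion/deletion in a population VCF,
polymorphic SSRs can be mined directly from resequencing variants instead
of from a reference scan. `ssrmine` implements that whole route:

1. **Repeat mining** — MISA-compatible detection of perfect tandem repeats
   (minimum copies 10/6/5/5/5/5 for mono- through hexanucleotide motifs),
   motif accounting with reverse-complement pairing (`TAT/ATA`);
2. **Variant pipeline** — long-InDel extraction (|Δlen| > 10 bp), QC
   (QUAL > 40, GQ > 40, 5 ≤ DP ≤ 100, MAF/missing-rate rule), collapsing
   to `{chrom}_{pos}` loci, removal of mononucleotide and compound loci,
   and selection of loci with a secondary common genotype;
3. **Primer design** — tract ± 150 bp templates, 18–27 nt primers with
   nearest-neighbour Tm 57–61 °C and 100–300 bp products spanning the
   tract, plus post-filters for short products, homopolymer runs ≥ 4 and
   extreme GC;
4. **Diversity statistics** — per-locus N, Na, Ne = 1/Σp², Shannon's
   I = −Σp ln p, Ho, He = 1 − Σp², F = (He − Ho)/He and Botstein PIC,
   with PIC banding and marker screening (Na ≥ 3, PIC > 0.30);
5. **Population structure** — Nei (1972) distance, UPGMA with Newick
   output, three-level AMOVA, AMOVA-based pairwise Fst, per-cluster
   diversity, and Evanno ΔK post-processing of clustering log-likelihoods;
6. **Fingerprinting** — presence/absence (0/1) allele matrices and the
   panel discrimination rate;
7. **Synthetic data** — seeded generators for reference scaffolds with
   planted SSRs, population VCFs with planted QC violations, and
   Balding–Nichols genotype panels, each with a truth table, so the whole
   pipeline is testable without external data.

See `docs/methods.md` for the statistical conventions and their rationale.

## Worked example

Everything below runs from scratch in a few seconds; `simulate` writes
seeded synthetic inputs plus their truth tables.

```bash
ssrmine simulate --seed 7 --outdir demo
ssrmine mine     --fasta demo/reference.fasta --out hits.tsv
ssrmine qc       --vcf demo/population.vcf --outdir qc
ssrmine stats    --genotypes demo/genotypes.csv --out stats.tsv
ssrmine structure --genotypes demo/genotypes.csv \
                  --grouping demo/grouping.tsv --outdir struct
ssrmine fingerprint --genotypes demo/genotypes.csv --outdir fp
```

which prints:

```
wrote simulated inputs to demo
14 SSR hits (14 total) -> hits.tsv
4 loci after class filters -> qc/loci.tsv
20 loci, total Na 111, mean He 0.701, mean PIC 0.660 -> stats.tsv
AMOVA among-population share: 4.9% -> struct
discrimination rate 100.00% (149/149) -> fp
```

Reading the numbers: the mined hit table recovers all 14 planted tracts
(coordinates, motif, copy number and compound flag per row); after QC and
class filtering 4 loci survive — the planted mononucleotide tracts,
compound pairs, sub-threshold InDels and QC-failing sites are exactly the
ones removed. The 20-locus genotype panel (149 accessions, three
subpopulations at Balding–Nichols divergence 0.08) shows high mean
expected heterozygosity (0.701) and PIC (0.660), an among-population AMOVA
share of 4.9 % (low differentiation, consistent with the mild divergence
simulated), pairwise Fst of 0.041–0.059, and every accession separable by
its 0/1 allele fingerprint (discrimination rate 100.00 %). Per-locus
output starts:

```
locus_id  N        Na     Ne     I      Ho     He     F       PIC    pic_class
SSR01     149.000  5.000  3.323  1.321  0.785  0.699  -0.123  0.650  high
SSR02     148.000  3.000  2.931  1.087  0.649  0.659   0.015  0.585  high
```

The same functionality is importable (`ssrmine.find_ssrs`,
`ssrmine.apply_qc`, `ssrmine.panel_summary`, `ssrmine.amova`, …); the CLI
is a thin layer over the library and writes a provenance JSON (parameters,
version, input checksums) next to every output.

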