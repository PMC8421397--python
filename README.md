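# emvarkit

Variant-to-function analysis for GWAS loci: from a massively parallel
reporter assay (MPRA) library through enhancer and allelic-effect calling
to target-gene prioritization, plus the HSV transformation for time-course
genomics.

## The problem

Most GWAS associations land in non-coding sequence, where the causal
variant usually acts by modulating an enhancer, and the target gene is
rarely the nearest one. This package implements the computational pipeline
for resolving both questions:

1. **Library design** (`emvarkit.design`) — candidate variants are the
   GWAS lead SNPs plus every biallelic common proxy (MAF ≥ 5%) within
   50 kb and in strong LD (dosage r² > 0.8). Each allele is embedded at
   the centre of a 175-nt genomic fragment and assembled into a 230-nt
   synthesis oligo, `FLANK5–enh–LINKER–barcode–FLANK3`, with 18–19 unique
   10-nt barcodes per allele. Barcodes are rejection-sampled under the
   cloning constraints: no homopolymer run ≥ 3, no KpnI (`GGTACC`) or XbaI
   (`TCTAGA`) site in assembled context, no `TCT` suffix.
2. **Quantification** (`emvarkit.quantify`) — sequenced barcodes are
   reverse-complemented and exact-matched to the manifest; low-input
   barcodes are dropped; per-barcode enhancer activity is

   *activity* = log₂(output CPM) − log₂(input CPM)

   followed by quantile normalization across replicates.
3. **Calling** (`emvarkit.callers`) — per replicate, each allele's
   barcode activities are tested one-sided (Mann–Whitney U) against the
   pooled activity of all other barcodes, with Benjamini–Hochberg FDR.
   Elements with a consensus-significant enhancer allele are tested for
   allelic skew (two-sided, ref vs alt barcodes). Consensus calls require
   replicate concordance: significant in ≥ half of all technical
   replicates, or in ≥ 1 technical replicate of each biological batch. A
   variant passing all gates is an **EMVar** (enhancer-modulating variant).
4. **Integration** (`emvarkit.integrate`) — promoter-capture Hi-C
   interactions are kept when CHiCAGO-style score > 5 at any timepoint,
   cis, and ≤ 1 Mb. An EMVar links to a baited gene when a distal
   interaction end comes within 1 kb of the SNP. Combining contact with
   tissue-matched/mismatched eQTL evidence, genes are tiered Class I–IV
   (strict precedence), gated on expression > 1 TPM.
5. **Time-course** (`emvarkit.timecourse`) — TMM/CPM normalization, the
   published expression filters, the HSV transformation
   (V = max C_t, S = 1 − min C_t / V,
   H = 60·(2 + (C_first + C_second − C_last − V)/(V·S))·sign(C_second − C_first)),
   hue-sector pattern binning, fuzzy-c-means cluster assignment under the
   two-threshold membership rule, and 1-kb summit-centred ATAC peak
   harmonization.
6. **Synthetic data** (`emvarkit.synthdata`) — seeded generators with
   ground-truth labels: negative-binomial barcode counts with planted
   enhancer/allelic effects, LD-structured genotypes via
   copy-with-flip haplotypes, labelled interaction mixes, and
   archetype-driven time-course matrices. These make error control and
   recovery measurable.

## Worked example

The numbered drivers under `analysis/` run the pipeline end to end on
synthetic data and write tables under `results/`:

```sh
python analysis/01_design_library.py --seed 1
python analysis/02_call_emvars.py   --seed 1
python analysis/03_integrate_loci.py --seed 1
python analysis/04_timecourse_hsv.py --seed 1
```

Output from seed 1:

```
selected 20 candidate variants (5 leads) across 5 loci
designed 720 fragments (20 variants x 2 alleles x 18 barcodes), all [230] nt
enhancers: 43 called, 43 planted, 43 recovered
EMVars:    29 called, 28 planted, 28 recovered
false-positive EMVars: 1
interactions: 22 simulated, 13 kept (expected 13 by construction)
EMVar-promoter links: 5
gene classes (brain): {'I': 3, 'II': 2}
HSV: 300 genes; 300 dynamic; median saturation by archetype: down=0.244, flat=0.116, transient=0.179, up=0.225
fuzzy c-means: 97/300 genes pass the membership thresholds (>0.3 avg, >0.2 per replicate)
peak harmonisation: 40 calls -> 40 1-kb union peaks
```

Reading this: all planted enhancers and EMVars were recovered at these
effect sizes (2-fold allelic shift inside 4-fold enhancers) with one false
positive among 200 elements; interaction filtering kept exactly the rows
constructed to pass; every planted EMVar-promoter link was found and
classified; and flat-archetype genes show roughly half the HSV saturation
of genuinely dynamic ones.

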