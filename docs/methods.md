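# Methods

## MPRA activity model

Per-barcode enhancer activity is the log2 ratio of RNA output to DNA input
on the CPM scale:

    activity_b = log2(rna_cpm_b + c) - log2(dna_cpm_b + c)

The activity formula is sometimes printed as the log2 of a CPM *difference*;
that reading is undefined whenever input ≥ output and is inconsistent with
its use as a fold change, so the package computes the difference of logs and
keeps the literal difference form behind `activity_literal` /
`eq4_literal=True` purely for audit. The pseudocount `c` defaults to 1
CPM-unit; with `c = 0` barcodes with a zero on either side come back NaN
and are excluded from testing rather than clamped.

The low-input filter drops barcodes with raw DNA count below 10 by
default. The threshold is a free parameter of the protocol (`min_dna`),
logged whenever applied; alleles losing every barcode are flagged
untestable rather than silently absorbed.

Quantile normalization is applied across RNA replicate columns after the
activity computation. The normalization axis is isolated in one function
(`quantify.quantile_normalize`) so it can be moved if a different
convention is wanted; ties receive the mean of their tied order-statistic
means, which makes the operation idempotent.

## Statistical calling

**Enhancer test.** Within each replicate, each allele's barcode activities
are compared one-sided (greater) against a null distribution. The
comparison group for this test is a genuine design choice; the package's
default is the pooled activity of all *other* tested barcodes in that
replicate — a self-normalizing empirical null that needs no extra
controls. Excluding the tested allele's own barcodes keeps the two samples
disjoint. An explicit negative-control barcode set can be supplied instead
(`null_barcodes=`). Benjamini–Hochberg correction is applied across all
tested alleles within a replicate.

**Mann–Whitney engine.** Exact enumeration of the rank-sum null is used
when the combined sample size is ≤ 20 and the data are tie-free; otherwise
a tie-corrected normal approximation with continuity correction (the same
convention R's `wilcox.test` defaults to). At pipeline scale the
one-vs-rest tests share a single replicate-wide ranking
(`_groups_vs_rest_p`), which is algebraically the same U statistic and is
cross-checked against the pairwise path in the test suite.

**Allelic (EMVar) test.** Only elements with at least one
consensus-significant enhancer allele are tested — the enhancer gate. Ref
vs alt barcode activities, two-sided, BH across tested elements within
each replicate. The reported direction is the sign of the alt−ref median
activity over all replicates.

**Concordance rule.** A consensus call requires significance (q < 0.05) in
at least ⌈T/2⌉ of the T technical replicates, or in at least one technical
replicate of every biological batch. Rounding half up for odd T is the
conservative reading of "half of all technical replicates" and is fixed
here; the batch structure (e.g. five technicals split 3 + 2 over two
separately cloned libraries) is declared in `ReplicateDesign`.

## Oligo and barcode constraints

Assembled fragments are exactly 230 nt: 16 (5' flank) + 175 (enhancer
context) + 12 (linker) + 10 (barcode) + 17 (3' flank). The 175-nt context
places the variant at 0-based index 87 (87 bp each side); the reference
strand is always used. Barcode validity — no homopolymer run ≥ 3, no
KpnI/XbaI site, no `TCT` suffix — is screened in assembled context
(linker + barcode + 3' flank must contain exactly one copy of each site,
the linker's own), which is stricter than screening the bare barcode and
catches junction-spanning sites. The enhancer insert itself is genomic
sequence and may legitimately contain restriction sites; the guarantee
covers the cloning-critical region downstream of the insert.

## Candidate selection

Dosage r² (squared Pearson correlation of 0/1/2 genotype vectors,
pairwise-complete, undefined for monomorphic input) with inclusive 50-kb
window, strict r² > 0.8, MAF ≥ 0.05. r² is computed on genotype dosages
rather than phased haplotypes; with the unphased panels this pipeline
takes as input that is the only option that needs no phasing step, and at
r² > 0.8 the two definitions rarely disagree. A variant qualifying for
several loci keeps all its locus tags, which downstream class assignment
respects.

## Interaction filtering, linking and gene classes

Retention: max score over timepoints strictly > 5, same chromosome,
anchor distance ≤ 1 Mb. Distance is midpoint-to-midpoint by default
(`distance="edge"` is available); the choice only matters for interactions
straddling the 1-Mb boundary by less than a fragment length. EMVar-promoter
linking measures from the 1-based SNP point to the nearest base of the
distal fragment (0 inside), boundary inclusive at exactly 1,000 bp.

Class assignment is a pure truth table over four evidence flags, with
strict precedence I > II > III > IV:

| interacts | eQTL (matched tissue) | eQTL (other tissue) | class |
|---|---|---|---|
| ✓ | ✓ | · | I |
| ✓ | ✗ | ✓ | II |
| exactly one of interacts / matched eQTL | | | III |
| ✗ | ✗ | ✓ | IV |

"Interacts or matched eGene" for Class III is read as *exactly one* of the
two (both together is Class I; contact plus mismatched eQTL is Class II);
the precedence resolution is this package's documented choice, enforced by
an exhaustive 16-combination test. Every class is gated on expression
> 1 TPM at ≥ 1 timepoint in the relevant cell type; gated genes never
appear in any class. The tissue → {adipose, brain, other} map is data
(an argument), not hard-coded names.

## HSV transformation

Computed as in the module docstring; the published formulation names the
first, second and last timepoints of a four-point course, generalised here
to (first, second, last) of any ordered course with ≥ 3 points, which also
covers a 3-point course unchanged. Degeneracies are flagged, never
computed through: S = 0 → "static" (H undefined); C_second = C_first →
"static-onset" (the sign term is singular); all-zero profile →
"undefined". Hue is wrapped into [0, 360) by modulo. (H, S) are invariant
to positive scaling of the profile; V scales linearly. For display, V and
S are rank-scaled to [0, 1] via (rank − 1)/(n − 1) with average ranks for
ties, which preserves order and attains both extremes. Hue-sector binning
uses 6 equal sectors by default (configurable); degenerate features keep
their flag as the bin label.

## TMM

Standard trimmed mean of M-values: reference column = the one whose
upper-quartile CPM is closest to the mean upper quartile; per sample, M
and A over genes positive in both; 30% two-sided trim on M and 5% on A
(rank-based, intersection kept); precision-weighted mean of the surviving
M values; factors centred to product 1. Factors are *relative to library
size* (a uniformly scaled column is pure depth, factor 1);
`tmm_effective_libsize` returns libsize × factor, which recovers a planted
uniform scaling exactly. The implementation agrees with an independent
step-by-step reimplementation to 1e-8 in the tests and was cross-checked
against edgeR's `calcNormFactors` during development.

## Fuzzy clustering

Fuzzy c-means (Bezdek), fuzzifier m = 2, seeded Dirichlet membership
initialisation, convergence when the largest membership change < 1e-6.
Assignment uses the two-threshold rule: a gene joins its argmax cluster of
the replicate-averaged memberships only when that average is strictly
above 0.3 and the same cluster's membership is strictly above 0.2 in every
individual replicate; otherwise it stays unassigned. Both thresholds are
strict inequalities (an average of exactly 0.3 does not assign).

## Synthetic-data generators

All generators take an explicit seed and are bit-identical across runs.
Negative-binomial counts use the mean/dispersion parameterisation
(variance μ + φμ²).

* **MPRA counts.** DNA ~ NB(μ_DNA, φ) per barcode; the RNA mean is
  μ_DNA · 2^(enhancer_log2fc·1[enhancer] + allelic_log2fc·1[EMVar ∧ alt]),
  drawn independently per replicate, so non-enhancer activity is centred
  at 0 on the log2-ratio scale. Defaults: 18 barcodes/allele, five
  technical replicates over two biological batches (3 + 2), μ_DNA = 100,
  φ = 0.1 (≈ 33% per-barcode CV — a well-sequenced library), enhancer
  shift 2 log2 units, allelic shift 1 log2 unit. The generator does not
  emulate PCR jackpotting, barcode dropout correlated between DNA and RNA,
  or cell-type-specific trans environments, so passing tests demonstrate
  correctness of the statistical machinery under the stated noise model,
  not performance on any particular real library.
* **Genotypes.** Haplotypes are Bernoulli(maf); a proxy copies the lead
  haplotype and flips with the probability that targets r = √r² (solved
  from the closed-form correlation of flipped Bernoullis); dosage = sum of
  two haplotypes. Realised r² is recorded, never assumed. Fewer than 10
  samples is rejected as too unstable to label.
* **Interactions.** A labelled mix of passing cis interactions, far-cis
  (> 1 Mb), trans and low-score decoys, plus planted distal ends at a
  configurable offset from given EMVars. No distance-decay model is
  attempted; the mix exists to exercise the filters, not to resemble a
  contact map.
* **Time courses.** Four archetypes (monotone up, monotone down,
  transient, flat) on the log2 scale with per-gene jitter, converted to NB
  counts at a configurable depth.

## Problem sizes

The validation suite measures error control on 500 elements × 20 seeds
(18 barcodes/allele, 5 replicates) and recovery/power on a 3×3 grid of
effect sizes × barcode counts at 80 elements × 3 seeds per cell; these
sizes give binomial standard errors of well under 1 percentage point for
the null proportion and a few points for per-cell power, which the stated
Monte-Carlo margins absorb.

## Known limitations

Read alignment, interaction calling (CHiCAGO itself), peak calling and
differential-expression model fitting are out of scope: the pipeline
starts from counts, scored interactions and called peaks. Barcode matching
is exact-only (no Hamming-1 rescue, no UMIs). Indels and multi-nucleotide
variants are not designed. The per-replicate testing granularity and the
enhancer-test null are configuration-exposed choices, not claims about any
particular laboratory's analysis.
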