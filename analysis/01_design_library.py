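#!/usr/bin/env python
"""Design an MPRA library from simulated GWAS loci.

Simulates an LD-structured genotype panel around five lead SNPs, selects
candidate variants (within 50 kb, r^2 > 0.8, MAF >= 5%), and assembles the
230-nt oligo library with 18 barcodes per allele.  Writes the candidate
table, barcode manifest and library FASTA under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from emvarkit import design, synthdata
from emvarkit.design import GenotypePanel, Variant


def main(seed: int, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    lead_positions = [int(p) for p in (2e6, 4e6, 6e6, 8e6, 10e6)]
    # four proxies per lead straddling the r^2 > 0.8 retention rule
    proxy_r2 = [[0.95, 0.9, 0.85, 0.5] for _ in lead_positions]
    variants, dosages = synthdata.simulate_genotypes(
        500, lead_positions, proxy_r2, seed=seed)
    panel = GenotypePanel(variants.drop(columns=["lead_id", "target_r2",
                                                 "realized_r2", "is_lead"]),
                          dosages)
    leads = [Variant(v.Index, v.chrom, v.pos, v.ref, v.alt, is_lead=True)
             for v in variants[variants.is_lead].itertuples()]

    candidates = design.select_candidates(leads, panel)
    cand_table = pd.DataFrame(
        [(c.id, c.chrom, c.pos, c.ref, c.alt, round(c.maf, 4), lid, c.is_lead)
         for c in candidates for lid in c.locus_ids],
        columns=["variant_id", "chrom", "pos", "ref", "alt", "maf",
                 "locus_id", "is_lead"])
    cand_table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    print(f"selected {len(candidates)} candidate variants "
          f"({cand_table.is_lead.sum()} leads) across "
          f"{cand_table.locus_id.nunique()} loci")

    # synthetic genome covering all candidate windows
    contig_len = int(max(c.pos for c in candidates)) + 1000
    genome = {"chr1": "".join(rng.choice(list("ACGT"), contig_len))}
    # patch reference bases so each candidate's ref allele matches
    g = list(genome["chr1"])
    for c in candidates:
        g[c.pos - 1] = c.ref
    genome["chr1"] = "".join(g)

    manifest = design.build_manifest(candidates, genome,
                                     barcodes_per_allele=18, seed=seed)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    design.write_library_fasta(manifest, outdir / "library.fa")
    print(f"designed {len(manifest)} fragments "
          f"({len(candidates)} variants x 2 alleles x 18 barcodes), "
          f"all {manifest.sequence.str.len().unique().tolist()} nt")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    a = ap.parse_args()
    main(a.seed, a.out)
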