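#!/usr/bin/env python
"""Integrate EMVars with chromatin interactions and eQTLs into gene classes.

Simulates promoter-capture interactions around a set of genes (with trans,
far-cis and low-score decoys), filters them (score > 5 at any timepoint,
cis, <= 1 Mb), links planted EMVars to baited promoters through distal ends
within 1 kb, attaches a tissue-classed eQTL table, and assigns Class I-IV
gene support per locus.  Writes links and class tables under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from emvarkit import synthdata
from emvarkit.integrate import (
    EQTLRecord, assign_gene_classes, bin_emvars_to_loci, filter_interactions,
    interactions_to_bedpe, link_emvar_promoters,
)


def main(seed: int, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = pd.DataFrame({"gene": [f"G{i}" for i in range(8)],
                          "chrom": "chr1",
                          "tss": 2_000_000 + 500_000 * np.arange(8)})
    emvars = {f"rs{i}": ("chr1", int(2_050_000 + 500_000 * i))
              for i in range(5)}
    candidates = pd.DataFrame({
        "variant_id": list(emvars) + ["rs1"],
        "locus_id": [f"L{i % 2}" for i in range(5)] + ["L1"],
    })

    interactions, truth = synthdata.simulate_chic(
        genes, emvars, n_cis_near=8, n_cis_far=3, n_trans=3, n_low_score=3,
        seed=seed)
    kept = filter_interactions(interactions)
    interactions_to_bedpe(kept, outdir / "interactions_filtered.bedpe")
    print(f"interactions: {len(interactions)} simulated, {len(kept)} kept "
          f"(expected {int(truth.survives_filter.sum())} by construction)")

    links = link_emvar_promoters(emvars, kept)
    links.to_csv(outdir / "emvar_promoter_links.tsv", sep="\t", index=False)
    print(f"EMVar-promoter links: {len(links)}")

    # eQTL support: half matched-tissue, half other-tissue
    eqtls = []
    for i, (vid, g) in enumerate(zip(links["variant_id"], links["gene"])):
        if i % 2 == 0:
            eqtls.append(EQTLRecord(vid, g, "Brain_Hypothalamus", "brain"))
        else:
            eqtls.append(EQTLRecord(vid, g, "Adipose_Visceral", "adipose"))
    tpm = pd.DataFrame({"t0": rng.uniform(2, 30, 8), "t1": rng.uniform(2, 30, 8)},
                       index=genes["gene"])

    emvar_loci = bin_emvars_to_loci(list(emvars), candidates)
    classes = assign_gene_classes(emvar_loci, links, eqtls, tpm, "brain")
    out = pd.DataFrame([(a.gene, a.locus_id, a.cell_type, a.gene_class,
                         a.interacts, a.eqtl_matched, a.eqtl_other)
                        for a in classes],
                       columns=["gene", "locus_id", "cell_type", "class",
                                "interacts", "eqtl_matched", "eqtl_other"])
    out.to_csv(outdir / "gene_classes.tsv", sep="\t", index=False)
    counts = out["class"].value_counts().to_dict()
    print(f"gene classes (brain): {counts}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    a = ap.parse_args()
    main(a.seed, a.out)
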