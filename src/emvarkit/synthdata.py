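"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic given its seed and returns ground-truth
labels alongside the data, so parameter recovery and error control can be
measured.  Negative-binomial counts use the mean/dispersion
parameterisation with variance mu + phi * mu^2.

Defaults mirror the assay the pipeline analyses: 18 barcodes per allele,
five technical replicates split 3 + 2 across two biological (separately
cloned) batches, and allelic effects planted only inside active enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import design
from .callers import ReplicateDesign
from .integrate import ChicInteraction


@dataclass
class SimParams:
    n_loci: int = 5
    proxies_per_locus: int = 4
    barcodes_per_allele: int = 18
    n_tech_reps: int = 5          # total technical replicates
    n_bio_reps: int = 2           # biological batches the technicals split over
    dna_mean: float = 100.0
    nb_dispersion: float = 0.1    # phi in var = mu + phi mu^2 (~33% CV at mu=100)
    frac_enhancers: float = 0.2
    enhancer_log2fc: float = 2.0
    frac_emvars: float = 0.3      # fraction of enhancer elements with allelic effect
    allelic_log2fc: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_enhancers", "frac_emvars"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_loci", "proxies_per_locus", "barcodes_per_allele",
                     "n_tech_reps", "n_bio_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.dna_mean <= 0:
            raise ValueError("dna_mean must be > 0")

    def replicate_design(self) -> ReplicateDesign:
        """Distribute technical replicates over biological batches as evenly
        as possible (5 technicals over 2 batches -> 3 + 2)."""
        bio = {}
        for i in range(self.n_tech_reps):
            bio[f"rep{i + 1}"] = f"bio{i % self.n_bio_reps + 1}"
        return ReplicateDesign(bio)


def nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    """NB(mean, phi) with variance mu + phi mu^2."""
    mean = np.asarray(mean, dtype=float)
    if (mean <= 0).any():
        raise ValueError("negative-binomial mean must be positive")
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_manifest(params: SimParams, n_elements: int | None = None) -> pd.DataFrame:
    """Barcode manifest for ``n_elements`` biallelic elements (ref/alt)."""
    if n_elements is None:
        n_elements = params.n_loci * (1 + params.proxies_per_locus)
    ids = [f"el{i:04d}" for i in range(n_elements)]
    barcodes = design.generate_barcodes(
        2 * n_elements * params.barcodes_per_allele, seed=params.seed)
    rows, k = [], 0
    for eid in ids:
        for allele in ("ref", "alt"):
            for _ in range(params.barcodes_per_allele):
                rows.append((eid, allele, barcodes[k]))
                k += 1
    return pd.DataFrame(rows, columns=["element_id", "allele", "barcode"])


def simulate_mpra_counts(
    manifest: pd.DataFrame,
    params: SimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant enhancer and allelic effects, draw DNA and per-replicate RNA counts.

    DNA counts are NB(dna_mean, phi) per barcode.  The RNA mean per barcode
    is dna_mean * 2^(enhancer_log2fc * is_enhancer + allelic_log2fc *
    (is_emvar and alt allele)); each replicate is an independent NB draw.
    Returns (count table indexed by barcode with a DNA column and one
    column per replicate, truth table per element).
    """
    if manifest.groupby(["element_id", "allele"]).size().min() < 1:
        raise ValueError("manifest needs >= 1 barcode per allele")
    rng = np.random.default_rng(params.seed)
    elements = manifest["element_id"].unique()
    n_el = elements.size

    is_enh = rng.random(n_el) < params.frac_enhancers
    is_emv = is_enh & (rng.random(n_el) < params.frac_emvars)
    truth = pd.DataFrame(
        {"element_id": elements, "is_enhancer": is_enh, "is_emvar": is_emv,
         "planted_enh_log2fc": np.where(is_enh, params.enhancer_log2fc, 0.0),
         "planted_allelic_log2fc": np.where(is_emv, params.allelic_log2fc, 0.0)}
    ).set_index("element_id")

    shift = (
        truth.loc[manifest["element_id"], "planted_enh_log2fc"].to_numpy()
        + np.where(manifest["allele"].to_numpy() == "alt",
                   truth.loc[manifest["element_id"], "planted_allelic_log2fc"].to_numpy(),
                   0.0)
    )
    rna_mean = params.dna_mean * np.exp2(shift)

    counts = pd.DataFrame(index=pd.Index(manifest["barcode"], name="barcode"))
    counts["DNA"] = nb_draw(rng, np.full(len(manifest), params.dna_mean),
                            params.nb_dispersion)
    for rep in params.replicate_design().replicates:
        counts[rep] = nb_draw(rng, rna_mean, params.nb_dispersion)
    return counts, truth


def _flip_prob_for_r(p: float, r_target: float) -> float:
    """Flip probability eps giving haplotype correlation r_target when the
    proxy copies a Bernoulli(p) lead allele and flips with probability eps."""
    if r_target >= 1.0:
        return 0.0

    def corr(eps):
        q = p * (1 - eps) + (1 - p) * eps
        return (1 - 2 * eps) * np.sqrt(p * (1 - p) / (q * (1 - q)))

    return brentq(lambda e: corr(e) - r_target, 0.0, 0.5)


def simulate_genotypes(
    n_samples: int,
    lead_positions: list[int],
    proxy_r2: list[list[float]],
    seed: int = 0,
    maf: float = 0.5,
    chrom: str = "chr1",
    proxy_spacing: int = 5_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LD-structured diploid dosages via copy-with-flip on haplotypes.

    For each lead (Bernoulli(maf) haplotypes) every requested proxy copies
    the lead haplotype and flips with the probability that targets
    sqrt(r2); dosage = sum of two independent haplotypes.  Realised
    lead-proxy dosage r^2 is reported in the variant table, not assumed.

    Returns (variant metadata with columns chrom/pos/ref/alt/lead_id/
    target_r2/realized_r2, dosage matrix samples x variants).
    """
    if n_samples < 10:
        raise ValueError("n_samples < 10: realised r^2 too unstable")
    rng = np.random.default_rng(seed)
    meta_rows, dosage_cols = [], {}
    for li, (pos, r2s) in enumerate(zip(lead_positions, proxy_r2)):
        lead_id = f"lead{li}"
        hap = rng.random((n_samples, 2)) < maf
        lead_dos = hap.sum(axis=1)
        dosage_cols[lead_id] = lead_dos
        meta_rows.append((lead_id, chrom, pos, "A", "G", lead_id, 1.0, 1.0, True))
        for pj, r2 in enumerate(r2s):
            eps = _flip_prob_for_r(maf, float(np.sqrt(r2)))
            flips = rng.random((n_samples, 2)) < eps
            prox = np.where(flips, ~hap, hap).sum(axis=1)
            vid = f"lead{li}_proxy{pj}"
            dosage_cols[vid] = prox
            realized = design.compute_r2(lead_dos, prox)
            meta_rows.append((vid, chrom, pos + (pj + 1) * proxy_spacing, "A", "G",
                              lead_id, r2, realized, False))
    variants = pd.DataFrame(
        meta_rows,
        columns=["id", "chrom", "pos", "ref", "alt", "lead_id",
                 "target_r2", "realized_r2", "is_lead"],
    ).set_index("id")
    dosages = pd.DataFrame(dosage_cols, index=[f"s{i}" for i in range(n_samples)])
    return variants, dosages


def simulate_chic(
    genes: pd.DataFrame,
    emvar_positions: dict[str, tuple[str, int]],
    n_cis_near: int = 10,
    n_cis_far: int = 3,
    n_trans: int = 3,
    n_low_score: int = 3,
    n_timepoints: int = 3,
    link_offset: int = 500,
    cell_type: str = "brain",
    seed: int = 0,
) -> tuple[list[ChicInteraction], pd.DataFrame]:
    """Labelled mix of cHi-C interactions straddling the retention rules.

    ``genes`` needs columns gene/chrom/tss.  Emits ``n_cis_near`` passing
    interactions (cis, <= 1 Mb, max score > 5), plus far-cis, trans and
    low-score decoys, plus one passing interaction per planted EMVar whose
    distal end sits ``link_offset`` bp from the SNP.  Returns the list and
    a truth table with a ``survives_filter``/``planted_link`` label per row.
    """
    if genes.empty:
        raise ValueError("gene list must be non-empty")
    rng = np.random.default_rng(seed)
    frag = 4_000
    out, truth = [], []

    def bait_for(row):
        return row.chrom, int(row.tss - frag // 2), int(row.tss + frag // 2)

    def add(kind, chrom_d, start_d, passing, gene_row, scores, planted=""):
        out.append(ChicInteraction(*bait_for(gene_row), chrom_d, start_d,
                                   start_d + frag, gene_row.gene,
                                   tuple(scores), cell_type))
        truth.append((gene_row.gene, kind, passing, planted))

    gene_cycle = list(genes.itertuples(index=False))
    for i in range(n_cis_near):
        g = gene_cycle[i % len(gene_cycle)]
        dist = int(rng.integers(50_000, 900_000))
        scores = rng.uniform(0.0, 4.5, n_timepoints)
        scores[rng.integers(n_timepoints)] = rng.uniform(5.5, 15.0)
        add("cis_near", g.chrom, int(g.tss + dist), True, g, scores)
    for i in range(n_cis_far):
        g = gene_cycle[i % len(gene_cycle)]
        scores = rng.uniform(5.5, 15.0, n_timepoints)
        add("cis_far", g.chrom, int(g.tss + 1_200_000 + i * 50_000), False, g, scores)
    for i in range(n_trans):
        g = gene_cycle[i % len(gene_cycle)]
        scores = rng.uniform(5.5, 15.0, n_timepoints)
        add("trans", "chrT", int(rng.integers(1_000_000, 5_000_000)), False, g, scores)
    for i in range(n_low_score):
        g = gene_cycle[i % len(gene_cycle)]
        scores = rng.uniform(0.1, 4.9, n_timepoints)
        add("low_score", g.chrom, int(g.tss + 100_000 + i * 10_000), False, g, scores)

    for j, (vid, (chrom, pos)) in enumerate(sorted(emvar_positions.items())):
        g = gene_cycle[j % len(gene_cycle)]
        if g.chrom != chrom:
            g = next((x for x in gene_cycle if x.chrom == chrom), g)
        start_d = pos - 1 + link_offset  # distal end link_offset bp beyond the SNP
        scores = rng.uniform(5.5, 15.0, n_timepoints)
        add("planted_link", chrom, start_d, True, g, scores, planted=vid)

    truth_df = pd.DataFrame(truth, columns=["gene", "kind", "survives_filter",
                                            "planted_link"])
    return out, truth_df


ARCHETYPES = ("up", "down", "transient", "flat")


def archetype_profile(kind: str, n_timepoints: int, amplitude: float = 3.0,
                      baseline: float = 4.0) -> np.ndarray:
    """Noise-free log2 expression profile of one temporal archetype."""
    t = np.linspace(0.0, 1.0, n_timepoints)
    if kind == "up":
        prof = baseline + amplitude * t
    elif kind == "down":
        prof = baseline + amplitude * (1.0 - t)
    elif kind == "transient":
        prof = baseline + amplitude * np.sin(np.pi * t)
    elif kind == "flat":
        prof = np.full(n_timepoints, baseline)
    else:
        raise ValueError(f"unknown archetype {kind!r}")
    return prof


def simulate_timecourse(
    n_genes: int = 100,
    n_timepoints: int = 4,
    n_reps: int = 3,
    pattern_mix: dict[str, float] | None = None,
    seed: int = 0,
    dispersion: float = 0.1,
    depth: float = 3e5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Count matrix of genes drawn from temporal archetypes with NB noise.

    Columns are labelled ``t{i}_r{j}``.  Returns (counts, truth archetype
    label per gene).
    """
    if n_timepoints < 3:
        raise ValueError("need >= 3 timepoints (hue undefined below three)")
    mix = pattern_mix or {k: 0.25 for k in ARCHETYPES}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("pattern_mix must sum to 1")
    rng = np.random.default_rng(seed)
    kinds = rng.choice(list(mix), size=n_genes, p=list(mix.values()))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    cols = [f"t{i}_r{j}" for i in range(n_timepoints) for j in range(n_reps)]
    mean_expr = np.empty((n_genes, n_timepoints))
    for i, kind in enumerate(kinds):
        jitter = rng.normal(0.0, 0.3)
        mean_expr[i] = archetype_profile(kind, n_timepoints) + jitter
    lin = np.exp2(mean_expr)
    lin = lin / lin.sum(axis=0) * depth  # scale to a sequencing depth
    counts = np.empty((n_genes, n_timepoints * n_reps), dtype=np.int64)
    for ti in range(n_timepoints):
        for rj in range(n_reps):
            counts[:, ti * n_reps + rj] = nb_draw(rng, lin[:, ti], dispersion)
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=cols)
    return df, pd.Series(kinds, index=df.index, name="archetype")


def timepoint_map(columns) -> dict[str, str]:
    """Map ``t{i}_r{j}`` sample names to their timepoint label."""
    return {c: c.split("_")[0] for c in columns}
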