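"""Chromatin-interaction filtering, EMVar-promoter linking and gene classes.

Promoter-capture Hi-C interactions are retained when their CHiCAGO-style
score exceeds 5 at any timepoint, both anchors share a chromosome, and the
anchors lie within 1 Mb.  An EMVar is linked to a baited gene when the
distal end of one of that gene's interactions comes within 1 kb of the SNP.
Genes are then tiered per locus and cell type:

    Class I    EMVar contacts the gene AND is an eQTL for it in the matched
               tissue class
    Class II   contact plus an eQTL only in other tissue classes
    Class III  exactly one of {contact, matched eQTL}
    Class IV   eQTL in other tissue classes only
    unclassified otherwise

with strict precedence I > II > III > IV, and every class gated on the gene
being expressed above 1 TPM at one or more timepoints in that cell type.

All intervals are 0-based half-open (BED/BEDPE convention); SNP positions
are 1-based (VCF convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHIC_SCORE_MIN = 5.0
CHIC_MAX_DIST = 1_000_000
LINK_WINDOW = 1_000
TPM_GATE = 1.0


@dataclass(frozen=True)
class ChicInteraction:
    """One baited-promoter interaction with per-timepoint scores."""

    chrom_bait: str
    start_bait: int
    end_bait: int
    chrom_distal: str
    start_distal: int
    end_distal: int
    gene: str
    scores: tuple[float, ...]
    cell_type: str = "brain"

    def __post_init__(self):
        if self.start_bait >= self.end_bait or self.start_distal >= self.end_distal:
            raise ValueError(f"malformed interval in interaction for {self.gene}")

    @property
    def is_cis(self) -> bool:
        return self.chrom_bait == self.chrom_distal

    def midpoint_distance(self) -> float:
        if not self.is_cis:
            return float("inf")
        mid_b = (self.start_bait + self.end_bait) / 2.0
        mid_d = (self.start_distal + self.end_distal) / 2.0
        return abs(mid_b - mid_d)

    def edge_distance(self) -> float:
        if not self.is_cis:
            return float("inf")
        if self.end_bait <= self.start_distal:
            return float(self.start_distal - self.end_bait)
        if self.end_distal <= self.start_bait:
            return float(self.start_bait - self.end_distal)
        return 0.0


def filter_interactions(
    raw: list[ChicInteraction],
    score_min: float = CHIC_SCORE_MIN,
    max_dist: int = CHIC_MAX_DIST,
    distance: str = "midpoint",
) -> list[ChicInteraction]:
    """Keep cis interactions within ``max_dist`` whose max score > ``score_min``.

    Distance between the two anchors is measured midpoint-to-midpoint by
    default (``distance="edge"`` switches to edge-to-edge).  Idempotent.
    """
    dist_fn = {"midpoint": ChicInteraction.midpoint_distance,
               "edge": ChicInteraction.edge_distance}[distance]
    return [
    x for x in raw
        if max(x.scores) > score_min and x.is_cis and dist_fn(x) <= max_dist
    ]


def point_interval_distance(pos_1based: int, start: int, end: int) -> int:
    """Distance in bp from a 1-based point to a 0-based half-open interval.

    Zero when the point falls inside the interval.
    """
    p = pos_1based - 1
    if start <= p < end:
        return 0
    return start - p if p < start else p - (end - 1)


def link_emvar_promoters(
    emvar_positions: dict[str, tuple[str, int]],
    interactions: list[ChicInteraction],
    window: int = LINK_WINDOW,
) -> pd.DataFrame:
    """Link EMVars to baited genes via distal interaction ends.

    ``emvar_positions`` maps variant id to (chrom, 1-based position).  A
    link is made when the SNP lies within ``window`` bp of the distal
    fragment (boundary inclusive: exactly 1,000 bp links).  Interactions
    should already be filtered.  Returns one row per (variant, gene,
    cell_type) with the minimal distance achieving the link.
    """
    rows = []
    for vid, (chrom, pos) in emvar_positions.items():
        for x in interactions:
            if x.chrom_distal != chrom:
                continue
            d = point_interval_distance(pos, x.start_distal, x.end_distal)
            if d <= window:
                rows.append((vid, x.gene, x.cell_type, d))
    df = pd.DataFrame(rows, columns=["variant_id", "gene", "cell_type", "distance"])
    if df.empty:
        return df
    return (
        df.groupby(["variant_id", "gene", "cell_type"], as_index=False)["distance"]
        .min()
    )


def _intervals_overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def link_promoter_atac(
    interactions: list[ChicInteraction],
    peaks: pd.DataFrame,
) -> pd.Series:
    """Count distinct ATAC peaks contacted by each baited promoter.

    ``peaks`` needs columns chrom/start/end and a unique ``peak_id``.  A
    peak counts for a gene when it overlaps the distal end of any of that
    gene's interactions, at any timepoint; the same peak reachable through
    several interactions counts once.
    """
    hits: dict[str, set[str]] = {}
    for x in interactions:
        hits.setdefault(x.gene, set())
        sub = peaks[peaks["chrom"] == x.chrom_distal]
        for pk in sub.itertuples(index=False):
            if _intervals_overlap(x.start_distal, x.end_distal, pk.start, pk.end):
                hits[x.gene].add(pk.peak_id)
    return pd.Series({g: len(s) for g, s in hits.items()}, name="n_peaks").sort_index()


@dataclass(frozen=True)
class EQTLRecord:
    variant_id: str
    gene: str
    tissue: str
    tissue_class: str  # {"adipose", "brain", "other"} via an explicit map


def classify_tissues(eqtls: pd.DataFrame, tissue_class_map: dict[str, str]) -> list[EQTLRecord]:
    """Attach a tissue class to each eQTL row using the shipped tissue map."""
    out = []
    for row in eqtls.itertuples(index=False):
        cls = tissue_class_map.get(row.tissue, "other")
        out.append(EQTLRecord(row.variant_id, row.gene, row.tissue, cls))
    return out


@dataclass
class GeneClassAssignment:
    gene: str
    locus_id: str
    cell_type: str
    gene_class: str  # "I" | "II" | "III" | "IV" | "unclassified"
    interacts: bool
    eqtl_matched: bool
    eqtl_other: bool
    expressed: bool


def class_from_evidence(interacts: bool, eqtl_matched: bool,
                        eqtl_other: bool, expressed: bool) -> str:
    """Pure truth-table mapping of evidence flags to a support class."""
    if not expressed:
        return "unclassified"
    if interacts and eqtl_matched:
        return "I"
    if interacts and eqtl_other:
        return "II"
    if interacts != eqtl_matched:  # exactly one of the two
        return "III"
    if eqtl_other:
        return "IV"
    return "unclassified"


def bin_emvars_to_loci(
    emvar_ids: list[str],
    candidates: pd.DataFrame,
) -> dict[str, list[str]]:
    """Map each EMVar to every locus its variant qualified for.

    ``candidates`` carries ``variant_id`` and ``locus_id`` columns from the
    library-design step; an EMVar in LD with two leads appears under both.
    """
    table = candidates.groupby("variant_id")["locus_id"].apply(list)
    out = {}
    for vid in emvar_ids:
        if vid not in table.index:
            raise KeyError(f"EMVar {vid} absent from candidate table")
        out[vid] = sorted(set(table[vid]))
    return out


def assign_gene_classes(
    emvar_loci: dict[str, list[str]],
    links: pd.DataFrame,
    eqtls: list[EQTLRecord],
    expression_tpm: pd.DataFrame,
    cell_type: str,
) -> list[GeneClassAssignment]:
    """Assign Class I-IV support per (gene, locus) for one cell type.

    Evidence flags aggregate over all EMVars of the locus: ``interacts``
    (any EMVar-promoter contact in this cell type's libraries),
    ``eqtl_matched`` (any EMVar is an eQTL for the gene in the matched
    tissue class), ``eqtl_other`` (in any other tissue class).  Genes not
    expressed above 1 TPM at one or more timepoints are excluded from every
    class; genes absent from the expression table are excluded with a
    warning.
    """
    link_pairs = set()
    if not links.empty:
        sub = links[links["cell_type"] == cell_type]
        link_pairs = set(zip(sub["variant_id"], sub["gene"]))

    eqtl_matched_pairs = {(e.variant_id, e.gene) for e in eqtls
                          if e.tissue_class == cell_type}
    eqtl_other_pairs = {(e.variant_id, e.gene) for e in eqtls
                        if e.tissue_class != cell_type}

    genes = sorted(
        {g for _, g in link_pairs}
        | {e.gene for e in eqtls}
    )

    out = []
    for gene in genes:
        if gene not in expression_tpm.index:
            warnings.warn(f"gene {gene} missing from expression table; excluded")
            continue
        expressed = bool((expression_tpm.loc[gene] > TPM_GATE).any())
        touched: dict[str, dict[str, bool]] = {}
        for vid, loci in emvar_loci.items():
            interacts = (vid, gene) in link_pairs
            m = (vid, gene) in eqtl_matched_pairs
            o = (vid, gene) in eqtl_other_pairs
            if not (interacts or m or o):
                continue
            for locus in loci:
                fl = touched.setdefault(locus, {"i": False, "m": False, "o": False})
                fl["i"] |= interacts
                fl["m"] |= m
                fl["o"] |= o
        for locus, fl in sorted(touched.items()):
            cls = class_from_evidence(fl["i"], fl["m"], fl["o"], expressed)
            if not expressed:
                continue  # gated genes never enter any class
            out.append(GeneClassAssignment(gene, locus, cell_type, cls,
                                           fl["i"], fl["m"], fl["o"], expressed))
    return out


def interactions_to_bedpe(interactions: list[ChicInteraction], path) -> None:
    rows = []
    for x in interactions:
        rows.append([x.chrom_bait, x.start_bait, x.end_bait,
                     x.chrom_distal, x.start_distal, x.end_distal,
                     x.gene, x.cell_type] + list(x.scores))
    n_tp = max(len(x.scores) for x in interactions) if interactions else 0
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "gene", "cell_type"] + [f"score_tp{i}" for i in range(n_tp)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def bedpe_to_interactions(path) -> list[ChicInteraction]:
    df = pd.read_csv(path, sep="\t")
    score_cols = [c for c in df.columns if c.startswith("score_tp")]
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(ChicInteraction(
                row.chrom1, int(row.start1), int(row.end1),
                row.chrom2, int(row.start2), int(row.end2),
                row.gene, tuple(float(getattr(row, c)) for c in score_cols),
                row.cell_type))
        except (ValueError, TypeError) as e:
            raise ValueError(f"malformed BEDPE row {i + 2}: {e}") from e
    return out
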