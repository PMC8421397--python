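"""MPRA library design: LD-proxy candidate selection and constrained oligo assembly.

Candidate variants are the GWAS lead SNPs plus every biallelic panel variant
within 50 kb of a lead, in strong LD with it (dosage r^2 > 0.8) and common
(MAF >= 5%).  Each allele of each candidate is embedded at the centre of a
175-nt fragment of genomic context and assembled into a 230-nt synthesis
oligo together with a 10-nt barcode:

    5'-FLANK5 (16) - enh (175) - LINKER (12) - barcode (10) - FLANK3 (17)-3'

The linker carries single KpnI (GGTACC) and XbaI (TCTAGA) sites used during
cloning; barcodes must not recreate either site (checked in assembled
context), must not contain a homopolymer run of three or more bases, and
must not end in "TCT" (which would form a second XbaI site against the
3' constant region).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FLANK5 = "ACTGGCCGCTTCACTG"
LINKER = "GGTACCTCTAGA"
FLANK3 = "AGATCGGAAGAGCGTCG"
ENH_LEN = 175
BARCODE_LEN = 10
OLIGO_LEN = len(FLANK5) + ENH_LEN + len(LINKER) + BARCODE_LEN + len(FLANK3)  # 230

KPNI_SITE = "GGTACC"
XBAI_SITE = "TCTAGA"

_ACGT = re.compile(r"^[ACGT]*$")
_HOMOPOLYMER = re.compile(r"(.)\1\1")


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP tagged with the GWAS locus (lead SNP) it belongs to."""

    id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    maf: float = np.nan
    locus_ids: tuple[str, ...] = field(default_factory=tuple)
    is_lead: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if "," in self.alt:
            raise ValueError(f"variant {self.id} is multiallelic (alt={self.alt})")
        if np.isfinite(self.maf) and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"MAF must be in [0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class OligoFragment:
    element_id: str
    allele: str
    barcode: str
    enh: str
    sequence: str


def compute_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two genotype dosage vectors.

    Missing values (NaN) are dropped pairwise-complete.  Returns NaN when
    fewer than two complete pairs remain or when either vector is
    monomorphic (zero variance), in which case r^2 is undefined.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2:
        return float("nan")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


class GenotypePanel:
    """Dosage matrix (samples x variants) plus per-variant metadata.

    ``variants`` is a DataFrame indexed by variant id with columns
    ``chrom``, ``pos``, ``ref``, ``alt``; ``dosages`` is a DataFrame of
    0/1/2 dosages with samples as rows and variant ids as columns.
    """

    def __init__(self, variants: pd.DataFrame, dosages: pd.DataFrame):
        missing = set(variants.index) - set(dosages.columns)
        if missing:
            raise ValueError(f"variants absent from dosage matrix: {sorted(missing)[:5]}")
        self.variants = variants
        self.dosages = dosages

    def maf(self, vid: str) -> float:
        d = self.dosages[vid].to_numpy(dtype=float)
        d = d[~np.isnan(d)]
        if d.size == 0:
            return float("nan")
        p = d.mean() / 2.0
        return float(min(p, 1.0 - p))

    def is_biallelic(self, vid: str) -> bool:
        alt = str(self.variants.loc[vid, "alt"])
        return "," not in alt and len(alt.split("/")) == 1


def select_candidates(
    leads: list[Variant],
    panel: GenotypePanel,
    window: int = 50_000,
    r2_min: float = 0.8,
    maf_min: float = 0.05,
) -> list[Variant]:
    """Select MPRA candidate variants: each lead plus its LD proxies.

    A panel variant qualifies for a locus when it is biallelic, lies within
    ``window`` bp of the lead (inclusive), has dosage r^2 strictly greater
    than ``r2_min`` with the lead and MAF >= ``maf_min``.  A variant
    qualifying for several loci is emitted once with all its locus tags.
    Leads are always emitted (r^2 with self is 1), with a warning if a lead
    is missing from the panel.
    """
    import warnings

    locus_map: dict[str, set[str]] = {}
    meta: dict[str, Variant] = {}

    for lead in leads:
        locus = lead.id
        locus_map.setdefault(lead.id, set()).add(locus)
        meta.setdefault(
            lead.id,
            Variant(lead.id, lead.chrom, lead.pos, lead.ref, lead.alt,
                    maf=lead.maf, is_lead=True),
        )
        if lead.id not in panel.dosages.columns:
            warnings.warn(f"lead {lead.id} absent from genotype panel; emitted alone")
            continue
        lead_dos = panel.dosages[lead.id]
        neighborhood = panel.variants[
            (panel.variants["chrom"] == lead.chrom)
            & ((panel.variants["pos"] - lead.pos).abs() <= window)
        ]
        for vid, row in neighborhood.iterrows():
            if vid == lead.id or not panel.is_biallelic(vid):
                continue
            if panel.maf(vid) < maf_min:
                continue
            r2 = compute_r2(lead_dos, panel.dosages[vid])
            if np.isnan(r2) or r2 <= r2_min:
                continue
            locus_map.setdefault(vid, set()).add(locus)
            meta.setdefault(
                vid,
                Variant(vid, str(row["chrom"]), int(row["pos"]), str(row["ref"]),
                        str(row["alt"]), maf=panel.maf(vid)),
            )

    out = []
    for vid in sorted(locus_map):
        v = meta[vid]
        out.append(
            Variant(v.id, v.chrom, v.pos, v.ref, v.alt, maf=v.maf,
                    locus_ids=tuple(sorted(locus_map[vid])), is_lead=v.is_lead)
        )
    return out


def is_valid_barcode(seq: str, length: int = BARCODE_LEN) -> bool:
    """Check a candidate barcode against the synthesis constraints.

    Valid iff: expected length; no run of three or more identical bases;
    neither restriction site (KpnI GGTACC, XbaI TCTAGA) appears in the
    barcode or at its junctions with the linker and 3' constant region
    (screened on LINKER + barcode + FLANK3, requiring exactly the single
    designed occurrence of each site); and the barcode does not end "TCT".
    """
    if not _ACGT.match(seq):
        raise ValueError(f"barcode contains non-ACGT characters: {seq!r}")
    if len(seq) != length:
        return False
    if _HOMOPOLYMER.search(seq):
        return False
    if seq.endswith("TCT"):
        return False
    context = LINKER + seq + FLANK3
    # the linker contributes one copy of each site by design
    if context.count(KPNI_SITE) != 1 or context.count(XBAI_SITE) != 1:
        return False
    return True


def _enumerate_valid(length: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=length)
            if is_valid_barcode("".join(p), length=length)]


def generate_barcodes(n: int, seed: int, length: int = BARCODE_LEN) -> list[str]:
    """Draw ``n`` distinct valid barcodes by seeded rejection sampling."""
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    bases = np.array(list("ACGT"))
    # generous attempt budget; the valid 10-mer pool is ~hundreds of thousands
    max_attempts = 500 * n + 100_000
    attempts = 0
    while len(out) < n and attempts < max_attempts:
        batch = rng.integers(0, 4, size=(max(256, n - len(out)), length))
        attempts += batch.shape[0]
        for row in batch:
            bc = "".join(bases[row])
            if bc in seen or not is_valid_barcode(bc, length=length):
                continue
            seen.add(bc)
            out.append(bc)
            if len(out) == n:
                break
    if len(out) < n:
        if length <= 8:
            pool = len(_enumerate_valid(length))
            raise ValueError(
                f"cannot draw {n} distinct valid barcodes of length {length}; "
                f"achievable maximum is {pool}")
        raise ValueError(f"cannot draw {n} distinct valid barcodes of length {length}")
    return out


def extract_context(genome, v: Variant, allele: str, flank: int = ENH_LEN // 2) -> str:
    """Cut the 175-nt genomic window centred on a SNP, substituting the allele.

    ``genome`` maps chromosome name to sequence (a plain dict or a pyfaidx
    Fasta both work).  The variant base sits at 0-based index ``flank`` (87)
    of the returned fragment.  SNVs only; the window must fit in the contig.
    """
    if len(v.ref) != 1 or len(allele) != 1:
        raise ValueError(f"{v.id}: only single-nucleotide substitutions supported")
    contig = str(genome[v.chrom][:]) if hasattr(genome[v.chrom], "__getitem__") else str(genome[v.chrom])
    i = v.pos - 1  # to 0-based
    if i - flank < 0 or i + flank + 1 > len(contig):
        raise ValueError(f"{v.id}: window of {flank} bp each side exceeds contig bounds")
    left = contig[i - flank:i]
    right = contig[i + 1:i + flank + 1]
    ref_base = contig[i]
    if ref_base.upper() != v.ref.upper():
        raise ValueError(f"{v.id}: reference base {ref_base} does not match ref allele {v.ref}")
    return (left + allele + right).upper()


def build_oligo(element_id: str, allele: str, enh: str, barcode: str) -> OligoFragment:
    """Assemble the 230-nt synthesis fragment from enhancer context and barcode."""
    if len(enh) != ENH_LEN:
        raise ValueError(f"enh must be {ENH_LEN} nt, got {len(enh)}")
    if len(barcode) != BARCODE_LEN:
        raise ValueError(f"barcode must be {BARCODE_LEN} nt, got {len(barcode)}")
    if not is_valid_barcode(barcode):
        raise ValueError(f"barcode {barcode} fails validity rules in assembled context")
    seq = FLANK5 + enh + LINKER + barcode + FLANK3
    assert len(seq) == OLIGO_LEN
    return OligoFragment(element_id, allele, barcode, enh, seq)


def parse_oligo(sequence: str) -> tuple[str, str]:
    """Invert :func:`build_oligo`: recover (enh, barcode) from a 230-nt fragment."""
    if len(sequence) != OLIGO_LEN:
        raise ValueError(f"fragment must be {OLIGO_LEN} nt, got {len(sequence)}")
    if not sequence.startswith(FLANK5) or not sequence.endswith(FLANK3):
        raise ValueError("constant flanks not found")
    enh = sequence[len(FLANK5):len(FLANK5) + ENH_LEN]
    linker = sequence[len(FLANK5) + ENH_LEN:len(FLANK5) + ENH_LEN + len(LINKER)]
    if linker != LINKER:
        raise ValueError("linker not found at expected offset")
    barcode = sequence[len(FLANK5) + ENH_LEN + len(LINKER):-len(FLANK3)]
    return enh, barcode


def build_manifest(
    variants: list[Variant],
    genome,
    barcodes_per_allele: int = 18,
    seed: int = 0,
) -> pd.DataFrame:
    """Design the full library: every allele of every candidate gets
    ``barcodes_per_allele`` unique barcodes.

    Returns the barcode manifest (element_id, allele, barcode, sequence),
    one row per synthesised fragment.
    """
    n_alleles = 2 * len(variants)
    barcodes = generate_barcodes(n_alleles * barcodes_per_allele, seed=seed)
    rows = []
    k = 0
    for v in variants:
        for allele in (v.ref, v.alt):
            enh = extract_context(genome, v, allele)
            for _ in range(barcodes_per_allele):
                frag = build_oligo(v.id, allele, enh, barcodes[k])
                rows.append((v.id, allele, frag.barcode, frag.sequence))
                k += 1
    return pd.DataFrame(rows, columns=["element_id", "allele", "barcode", "sequence"])


def write_library_fasta(manifest: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in manifest.itertuples(index=False):
            fh.write(f">{row.element_id}|{row.allele}|{row.barcode}\n{row.sequence}\n")
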