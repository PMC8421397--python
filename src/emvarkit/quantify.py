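"""Barcode counting and per-barcode enhancer-activity quantification.

Sequenced barcode reads are reverse-complemented and exact-matched against
the library manifest; counts are normalised to counts-per-million (CPM) and
activity is the log2 ratio of RNA output CPM to DNA input CPM per barcode.
Activity columns are then quantile-normalised across RNA replicates.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def match_barcodes(
    reads,
    manifest: pd.DataFrame,
    offset: int = 0,
    barcode_length: int = 10,
) -> tuple[pd.Series, int]:
    """Count exact barcode matches in a pile of reads.

    Each read carries the barcode as a fixed-position slice starting at
    ``offset``; the slice is reverse-complemented before matching (the
    sequencer reads the barcode on the opposite strand).  Reads whose
    reverse-complemented slice is not an exact manifest barcode are tallied
    as unmatched, never rescued.

    Returns (counts indexed by manifest barcode, number of unmatched reads).
    """
    barcodes = manifest["barcode"]
    if barcodes.duplicated().any():
        dupes = barcodes[barcodes.duplicated()].unique()[:3]
        raise ValueError(f"manifest contains duplicate barcodes, e.g. {list(dupes)}")
    counts = pd.Series(0, index=pd.Index(barcodes, name="barcode"), dtype=np.int64)
    lookup = set(barcodes)
    unmatched = 0
    for read in reads:
        bc = reverse_complement(read[offset:offset + barcode_length])
        if bc in lookup:
            counts[bc] += 1
        else:
            unmatched += 1
    return counts, unmatched


def filter_low_barcodes(
    counts: pd.DataFrame,
    min_dna: int = 10,
    dna_col: str = "DNA",
    manifest: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Drop barcode rows whose DNA input count is below ``min_dna``.

    Logs the removed fraction.  If a manifest is supplied, alleles losing
    every barcode are flagged (they cannot be tested downstream).
    """
    if dna_col not in counts.columns:
        raise ValueError(f"DNA column {dna_col!r} not present")
    keep = counts[dna_col] >= min_dna
    removed = 1.0 - keep.mean() if len(keep) else 0.0
    log.info("filter_low_barcodes: removed %.1f%% of barcodes (DNA < %d)",
             100 * removed, min_dna)
    out = counts.loc[keep]
    if manifest is not None:
        surviving = set(out.index)
        lost = (
            manifest.groupby(["element_id", "allele"])["barcode"]
            .apply(lambda b: not any(x in surviving for x in b))
        )
        for (eid, allele), gone in lost.items():
            if gone:
                warnings.warn(f"allele {eid}/{allele} lost all barcodes; untestable")
    return out


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million, column-wise: count / column sum * 1e6."""
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero library size in column(s) {bad}")
    return counts / libsize * 1e6


def activity(
    rna_cpm: pd.Series,
    dna_cpm: pd.Series,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-barcode enhancer activity: log2 (output CPM / input CPM).

    Computed as log2(rna + pseudocount) - log2(dna + pseudocount).  With a
    zero pseudocount, barcodes with zero CPM on either side come back NaN
    (undefined) rather than +-inf.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    r = rna_cpm.reindex(dna_cpm.index).to_numpy(dtype=float) + pseudocount
    d = dna_cpm.to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore"):
        vals = np.log2(r) - np.log2(d)
    vals[~np.isfinite(vals)] = np.nan
    return pd.Series(vals, index=dna_cpm.index)


def activity_literal(rna_cpm: pd.Series, dna_cpm: pd.Series) -> pd.Series:
    """Audit variant: log2 of the CPM difference (output - input).

    Undefined (NaN) whenever input CPM >= output CPM; retained only so the
    printed form of the activity formula can be compared against the log2
    ratio actually used.
    """
    diff = rna_cpm.reindex(dna_cpm.index) - dna_cpm
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log2(diff.to_numpy(dtype=float))
    vals[~np.isfinite(vals)] = np.nan
    return pd.Series(vals, index=dna_cpm.index)


def activity_table(
    counts: pd.DataFrame,
    dna_col: str = "DNA",
    pseudocount: float = 1.0,
    eq4_literal: bool = False,
) -> pd.DataFrame:
    """Activity for every RNA replicate column against the DNA input column."""
    norm = cpm(counts)
    rna_cols = [c for c in counts.columns if c != dna_col]
    fn = activity_literal if eq4_literal else activity
    kwargs = {} if eq4_literal else {"pseudocount": pseudocount}
    return pd.DataFrame(
        {c: fn(norm[c], norm[dna_col], **kwargs) for c in rna_cols},
        index=counts.index,
    )


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalisation across columns.

    Each column's values are replaced by the cross-column mean of the order
    statistics at their rank; ties receive the mean over their tied rank
    positions (implemented via average ranks and linear interpolation on
    the rank grid).  After normalisation every column has the same sorted
    values, and the operation is idempotent.
    """
    if table.shape[1] < 2:
        raise ValueError("quantile normalisation needs >= 2 columns")
    for c in table.columns:
        col = table[c].dropna()
        if len(col) and col.nunique() == 1:
            warnings.warn(f"column {c!r} has all-identical values; passes through")
    arr = table.to_numpy(dtype=float)
    n = arr.shape[0]
    mean_sorted = np.nanmean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr)
    grid = np.arange(1, n + 1, dtype=float)
    ranks = pd.DataFrame(arr).rank(method="average").to_numpy()
    for j in range(arr.shape[1]):
        out[:, j] = np.interp(ranks[:, j], grid, mean_sorted)
        out[np.isnan(arr[:, j]), j] = np.nan
    return pd.DataFrame(out, index=table.index, columns=table.columns)
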