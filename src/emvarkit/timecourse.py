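"""Time-course normalisation, HSV transformation and fuzzy clustering.

The HSV transformation maps each feature's temporal profile (C_t, log2
normalised expression/accessibility/interaction strength, t ordered) onto a
colour-wheel coordinate:

    V = max_t C_t                      maximal level
    S = 1 - min_t C_t / V              maximal fold change, in [0, 1]
    H = 60 * (2 + (C_first + C_second - C_last - V) / (V * S))
          * sign(C_second - C_first),  wrapped into [0, 360)

so hue encodes the shape of the trajectory, saturation its dynamic range
and value its magnitude.  The published formulation is written for a course
whose first, second and last timepoints are days 0/2/16 of adipogenesis; it
generalises to any ordered course by reading (first, second, last), which
covers a 3-point neuronal course (days 12/16/27) unchanged.  For display, V
and S are additionally rank-scaled to [0, 1].

Degenerate profiles are flagged rather than computed: S = 0 (flat) leaves H
undefined ("static"); C_second = C_first makes the sign term singular
("static-onset"); V = 0 leaves the whole point undefined.

TMM scale factors, the published CPM/TPM expression filters, the
fuzzy-c-means membership rules (assign to the argmax cluster only when the
replicate-averaged membership exceeds 0.3 and every individual replicate's
membership exceeds 0.2) and 1-kb ATAC summit-centred peak harmonisation
live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------- TMM / CPM

def cpm_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / counts.sum(axis=0) * 1e6


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_col=None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors, one per sample.

    For each sample against the reference column (by default the sample
    whose upper-quartile CPM is closest to the mean upper quartile), the
    log2 ratio M and log2 abundance A are computed over genes with positive
    counts in both; the most extreme ``trim_m`` of M values and ``trim_a``
    of A values (each side) are discarded and the factor is the
    precision-weighted mean of the remaining M.  Factors are centred so
    their product is 1.  A sample sharing no expressed genes with the
    reference gets factor 1 with a warning.
    """
    libsize = counts.sum(axis=0).astype(float)
    frac = counts.div(libsize, axis=1)
    if ref_col is None:
        uq = frac.apply(lambda c: np.quantile(c[c > 0], 0.75) if (c > 0).any() else 0.0)
        ref_col = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_col].to_numpy(dtype=float)
    n_ref = libsize[ref_col]

    log_factors = {}
    for col in counts.columns:
        obs = counts[col].to_numpy(dtype=float)
        n_obs = libsize[col]
        both = (obs > 0) & (ref > 0)
        if not both.any():
            warnings.warn(f"sample {col!r} shares no expressed genes with reference")
            log_factors[col] = 0.0
            continue
        o, r = obs[both], ref[both]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        n = m.size
        # double trim by rank on M and A (keep the intersection)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            log_factors[col] = 0.0
            continue
        f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
        log_factors[col] = 0.0 if abs(f) < 1e-10 else float(f)

    lf = pd.Series(log_factors)
    lf = lf - lf.mean()  # centre so the product of factors is 1
    return np.exp2(lf)


def tmm_effective_libsize(counts: pd.DataFrame, **kwargs) -> pd.Series:
    """Library size x TMM factor: the divisor that equalises samples.

    A column that is a uniform k-fold scaling of the reference has TMM
    factor 1 (pure depth, absorbed by library size) but effective library
    size k times the reference's, so normalising by this recovers the
    planted scaling exactly.
    """
    return counts.sum(axis=0).astype(float) * tmm_factors(counts, **kwargs)


def filter_for_clustering(counts: pd.DataFrame, max_low: int = 3) -> pd.DataFrame:
    """Drop genes with CPM < 1 in more than ``max_low`` samples."""
    low = (cpm_matrix(counts) < 1.0).sum(axis=1)
    return counts.loc[low <= max_low]


def filter_for_hsv(
    tpm: pd.DataFrame,
    timepoint_of: dict[str, str],
    min_mean_log2: float = 1.0,
) -> pd.DataFrame:
    """Drop genes whose replicate-mean log2(TPM) is below 1 at any timepoint.

    ``timepoint_of`` maps each sample column to its timepoint label.
    log2 of a zero TPM is -inf, which fails the gate as intended.
    """
    with np.errstate(divide="ignore"):
        l2 = np.log2(tpm.to_numpy(dtype=float))
    l2 = pd.DataFrame(l2, index=tpm.index, columns=tpm.columns)
    groups = l2.T.groupby(pd.Series(timepoint_of)).mean().T
    keep = (groups >= min_mean_log2).all(axis=1)
    return tpm.loc[keep]


# ------------------------------------------------------------------- HSV

@dataclass(frozen=True)
class HSVPoint:
    feature: str
    H: float          # degrees in [0, 360); NaN when undefined
    S: float
    V: float
    pattern: str      # "dynamic" | "static" | "static-onset" | "undefined"


def hsv_transform(c, feature: str = "") -> HSVPoint:
    """Map one ordered temporal profile onto (H, S, V)."""
    c = np.asarray(c, dtype=float)
    if c.size < 3:
        raise ValueError("need at least three timepoints (first, second, last)")
    if (c < 0).any():
        raise ValueError("profile values must be >= 0 (log2 normalised scale)")
    v = float(c.max())
    if v == 0:
        return HSVPoint(feature, np.nan, np.nan, 0.0, "undefined")
    s = float(1.0 - c.min() / v)
    if s == 0:
        return HSVPoint(feature, np.nan, 0.0, v, "static")
    first, second, last = c[0], c[1], c[-1]
    if second == first:
        return HSVPoint(feature, np.nan, s, v, "static-onset")
    h = 60.0 * (2.0 + (first + second - last - v) / (v * s)) * np.sign(second - first)
    return HSVPoint(feature, float(h % 360.0), s, v, "dynamic")


def hsv_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """HSV-transform every row of a feature x timepoint matrix.

    Adds rank-scaled copies of V and S in [0, 1] (average ranks, extremes
    attained) for display.
    """
    pts = [hsv_transform(profiles.loc[f].to_numpy(), f) for f in profiles.index]
    df = pd.DataFrame(
        {"H": [p.H for p in pts], "S_raw": [p.S for p in pts],
         "V_raw": [p.V for p in pts], "pattern": [p.pattern for p in pts]},
        index=profiles.index,
    )
    for col in ("V", "S"):
        raw = df[f"{col}_raw"]
        r = raw.rank(method="average")
        n_ok = r.notna().sum()
        df[f"{col}_rank"] = (r - 1) / (n_ok - 1) if n_ok > 1 else 0.5
    return df


def bin_patterns(hsv: pd.DataFrame, n_bins: int = 6) -> pd.Series:
    """Bin dynamic features into equal hue sectors; degenerate ones keep
    their flag ("static", "static-onset", "undefined") as the bin label."""
    width = 360.0 / n_bins
    labels = []
    for _, row in hsv.iterrows():
        if row["pattern"] != "dynamic":
            labels.append(row["pattern"])
        else:
            labels.append(f"sector_{int(row['H'] // width)}")
    return pd.Series(labels, index=hsv.index, name="pattern_bin")


# --------------------------------------------------------- fuzzy c-means

def fuzzy_cmeans(
    data: np.ndarray,
    n_clusters: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means (Bezdek) on rows of ``data``.

    Returns (centers [c, d], memberships [n, c]); memberships rows sum to 1.
    Seeded random membership initialisation, stopping when the largest
    membership change falls below ``tol``.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    u = rng.dirichlet(np.ones(n_clusters), size=n)
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d = np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=2)
        d = np.fmax(d, 1e-12)
        inv = d ** (-2.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(u_new - u).max() < tol:
            u = u_new
            break
        u = u_new
    return centers, u


@dataclass
class ClusterAssignment:
    gene: str
    cluster: int          # -1 when unassigned
    membership_avg: float
    membership_per_rep: tuple[float, ...]


def assign_clusters(
    memberships_per_rep: list[pd.DataFrame],
    avg_min: float = 0.3,
    rep_min: float = 0.2,
) -> list[ClusterAssignment]:
    """Apply the two-threshold membership rule.

    ``memberships_per_rep`` holds one gene x cluster membership table per
    replicate (same index/columns).  A gene joins its argmax cluster of the
    replicate-averaged memberships only when that average membership is
    strictly above ``avg_min`` and the same cluster's membership is
    strictly above ``rep_min`` in every individual replicate.
    """
    avg = sum(memberships_per_rep) / len(memberships_per_rep)
    for rep in memberships_per_rep:
        bad = (rep.sum(axis=1) - 1.0).abs() > 1e-3
        if bad.any():
            warnings.warn(f"{int(bad.sum())} membership rows do not sum to 1")
    out = []
    for gene in avg.index:
        best = avg.loc[gene].idxmax()
        a = float(avg.loc[gene, best])
        reps = tuple(float(r.loc[gene, best]) for r in memberships_per_rep)
        ok = a > avg_min and all(v > rep_min for v in reps)
        out.append(ClusterAssignment(gene, int(best) if ok else -1, a, reps))
    return out


# ------------------------------------------------------------ ATAC peaks

def harmonize_peaks(peaks: pd.DataFrame, width: int = 1000) -> pd.DataFrame:
    """Collapse per-timepoint peak calls into uniform summit-centred windows.

    ``peaks`` has columns chrom/start/end/summit/score (one row per peak
    call, any timepoint).  Overlapping calls are merged into union loci;
    within each locus the summit of the highest-scoring call defines a
    single [summit - width/2, summit + width/2) interval.  Missing summits
    fall back to the interval midpoint with a warning.
    """
    pk = peaks.copy()
    if pk["summit"].isna().any():
        warnings.warn("missing summits; falling back to interval midpoints")
        mid = ((pk["start"] + pk["end"]) // 2)
        pk["summit"] = pk["summit"].fillna(mid)
    half = width // 2
    rows = []
    for chrom, sub in pk.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_start, cur_end, members = None, None, []
        for r in sub.itertuples(index=False):
            if cur_start is None or r.start >= cur_end:
                if members:
                    rows.append(_locus_window(chrom, members, half))
                cur_start, cur_end, members = r.start, r.end, [r]
            else:
                cur_end = max(cur_end, r.end)
                members.append(r)
        if members:
            rows.append(_locus_window(chrom, members, half))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _locus_window(chrom, members, half):
    top = max(members, key=lambda r: r.score)
    s = int(top.summit)
    return (chrom, s - half, s + half)
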