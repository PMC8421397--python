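"""Enhancer and EMVar calling.

Per RNA replicate, each allele's barcode activities are tested one-sided
(greater) against the pooled activity of all other tested barcodes in that
replicate (Mann-Whitney U); Benjamini-Hochberg correction is applied within
the replicate.  Elements with at least one consensus-significant enhancer
allele are then tested for allelic skew (ref vs alt barcodes, two-sided),
again BH-corrected per replicate.  A call survives to consensus under the
replicate-concordance rule: significant (q < alpha) in at least half of all
technical replicates, or in at least one technical replicate of each
biological batch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

EXACT_MAX_N = 20  # exact rank-sum null enumerated up to this combined size


def mwu(x, y, alternative: str = "two_sided") -> float:
    """Mann-Whitney U p-value for samples ``x`` vs ``y``.

    Exact enumeration of the rank-sum null when the combined sample size is
    at most 20 and there are no ties; otherwise a tie-corrected normal
    approximation with continuity correction (matching R's wilcox.test
    defaults).  ``alternative`` is ``"greater"`` (x stochastically greater
    than y) or ``"two_sided"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "greater": "greater"}[alternative]
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        if x.size + y.size <= EXACT_MAX_N:
            log.debug("ties present; falling back to normal approximation")
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt, method=method,
                             use_continuity=(method == "asymptotic"))
    return float(min(res.pvalue, 1.0))


def _groups_vs_rest_p(values: np.ndarray, group_codes: np.ndarray,
                      n_groups: int, alternative: str = "greater") -> np.ndarray:
    """Vectorised one-pass MWU of every group against its complement.

    Ranks the whole replicate once (midranks for ties) and derives each
    group's U statistic from its rank sum; p-values use the tie-corrected
    normal approximation with continuity correction.  Agreement with the
    pairwise :func:`mwu` asymptotic path is exercised in the test suite.
    """
    N = values.size
    ranks = stats.rankdata(values)
    # tie correction term: sum(t^3 - t) over tie groups
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    rank_sums = np.bincount(group_codes, weights=ranks, minlength=n_groups)
    n1 = np.bincount(group_codes, minlength=n_groups).astype(float)
    n2 = N - n1
    u = rank_sums - n1 * (n1 + 1) / 2.0  # U of group vs rest
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        if alternative == "greater":
            z = (u - mu - 0.5) / sigma
            p = stats.norm.sf(z)
        else:
            z = (np.abs(u - mu) - 0.5) / sigma
            p = 2 * stats.norm.sf(z)
    p = np.where(sigma > 0, p, 1.0)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg FDR q-values (NaN-tolerant)."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class ReplicateDesign:
    """Technical replicates grouped into biological batches.

    ``bio_group`` maps each replicate name to its biological batch label,
    e.g. five technical replicates split 3 + 2 across two separately cloned
    input libraries.
    """

    bio_group: dict[str, str]

    @property
    def replicates(self) -> list[str]:
        return list(self.bio_group)

    @property
    def n_technical(self) -> int:
        return len(self.bio_group)

    @property
    def bio_groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rep, grp in self.bio_group.items():
            out.setdefault(grp, []).append(rep)
        return out


def concordance(sig_flags: dict[str, bool], design: ReplicateDesign) -> bool:
    """Replicate-concordance rule for consensus calls.

    True iff the call is significant in at least half of all technical
    replicates (ceil(T/2), the conservative reading for odd T) or in at
    least one technical replicate of every biological batch.
    """
    unknown = set(sig_flags) - set(design.bio_group)
    if unknown:
        raise ValueError(f"replicates missing from design: {sorted(unknown)}")
    t = design.n_technical
    n_sig = sum(bool(sig_flags.get(r, False)) for r in design.replicates)
    if n_sig >= math.ceil(t / 2):
        return True
    groups = design.bio_groups
    return all(
        any(sig_flags.get(r, False) for r in reps) for reps in groups.values()
    ) and len(groups) > 0


@dataclass
class ElementCall:
    element_id: str
    allele: str
    p: dict[str, float] = field(default_factory=dict)      # per replicate
    q: dict[str, float] = field(default_factory=dict)
    sig: dict[str, bool] = field(default_factory=dict)
    is_enhancer: bool = False
    tested: bool = True


@dataclass
class EMVarCall:
    variant_id: str
    p: dict[str, float] = field(default_factory=dict)
    q: dict[str, float] = field(default_factory=dict)
    sig: dict[str, bool] = field(default_factory=dict)
    direction: int = 0        # sign of median(alt) - median(ref) activity
    concordant: bool = False
    is_emvar: bool = False


def call_enhancers(
    activity: pd.DataFrame,
    manifest: pd.DataFrame,
    design: ReplicateDesign,
    null_barcodes=None,
    alpha: float = 0.05,
    min_barcodes: int = 5,
) -> list[ElementCall]:
    """One-sided enhancer test per allele, BH within replicate, concordance.

    The null distribution is the pooled activity of all other tested
    barcodes in the replicate, or an explicit negative-control barcode set
    when ``null_barcodes`` is given.  Alleles with fewer than
    ``min_barcodes`` surviving barcodes are reported untested.
    """
    man = manifest[manifest["barcode"].isin(activity.index)]
    groups = man.groupby(["element_id", "allele"])["barcode"].apply(list)

    tested_keys = [k for k, bcs in groups.items() if len(bcs) >= min_barcodes]
    untested_keys = [k for k in groups.index if k not in set(tested_keys)]

    calls = {k: ElementCall(k[0], k[1]) for k in tested_keys}

    if null_barcodes is None:
        # vectorised group-vs-rest path on the pooled empirical null
        bc_to_code: dict[str, int] = {}
        for code, k in enumerate(tested_keys):
            for bc in groups[k]:
                bc_to_code[bc] = code
        for rep in design.replicates:
            col = activity[rep].dropna()
            idx = [bc for bc in col.index if bc in bc_to_code]
            vals = col.loc[idx].to_numpy(dtype=float)
            codes = np.array([bc_to_code[bc] for bc in idx])
            p = _groups_vs_rest_p(vals, codes, len(tested_keys), "greater")
            q = bh_adjust(p)
            for code, k in enumerate(tested_keys):
                calls[k].p[rep] = float(p[code])
                calls[k].q[rep] = float(q[code])
                calls[k].sig[rep] = bool(q[code] < alpha)
    else:
        null_set = set(null_barcodes)
        for rep in design.replicates:
            col = activity[rep].dropna()
            null_vals = col.loc[col.index.isin(null_set)].to_numpy(dtype=float)
            ps = []
            for k in tested_keys:
                vals = col.reindex(groups[k]).dropna().to_numpy(dtype=float)
                ps.append(mwu(vals, null_vals, "greater"))
            qs = bh_adjust(ps)
            for k, pv, qv in zip(tested_keys, ps, qs):
                calls[k].p[rep] = float(pv)
                calls[k].q[rep] = float(qv)
                calls[k].sig[rep] = bool(qv < alpha)

    for k in tested_keys:
        calls[k].is_enhancer = concordance(calls[k].sig, design)
    out = [calls[k] for k in tested_keys]
    out += [ElementCall(k[0], k[1], tested=False) for k in untested_keys]
    return out


def call_emvars(
    activity: pd.DataFrame,
    enhancer_calls: list[ElementCall],
    manifest: pd.DataFrame,
    design: ReplicateDesign,
    alpha: float = 0.05,
) -> list[EMVarCall]:
    """Two-sided allelic test on enhancer-gated elements.

    Only elements with at least one consensus-significant enhancer allele
    are tested: ref-allele barcodes vs alt-allele barcodes, two-sided MWU
    per replicate, BH across tested elements within replicate, consensus by
    the concordance rule.  Elements missing one allele are skipped.
    """
    gated = sorted({c.element_id for c in enhancer_calls if c.is_enhancer})
    man = manifest[manifest["barcode"].isin(activity.index)]
    allele_order = manifest.drop_duplicates(["element_id", "allele"])

    testable = []
    for eid in gated:
        alleles = list(allele_order.loc[allele_order["element_id"] == eid, "allele"])
        if len(alleles) != 2:
            log.info("element %s lacks two alleles post-filter; skipped", eid)
            continue
        ref_a, alt_a = alleles[0], alleles[1]
        ref_bc = man.loc[(man["element_id"] == eid) & (man["allele"] == ref_a), "barcode"]
        alt_bc = man.loc[(man["element_id"] == eid) & (man["allele"] == alt_a), "barcode"]
        if len(ref_bc) == 0 or len(alt_bc) == 0:
            log.info("element %s lost all barcodes of one allele; skipped", eid)
            continue
        testable.append((eid, list(ref_bc), list(alt_bc)))

    calls = {eid: EMVarCall(eid) for eid, _, _ in testable}
    for rep in design.replicates:
        col = activity[rep].dropna()
        ps = []
        for eid, ref_bc, alt_bc in testable:
            rv = col.reindex(ref_bc).dropna().to_numpy(dtype=float)
            av = col.reindex(alt_bc).dropna().to_numpy(dtype=float)
            ps.append(mwu(rv, av, "two_sided") if rv.size and av.size else np.nan)
        qs = bh_adjust(ps)
        for (eid, _, _), pv, qv in zip(testable, ps, qs):
            calls[eid].p[rep] = float(pv)
            calls[eid].q[rep] = float(qv)
            calls[eid].sig[rep] = bool(qv < alpha) if np.isfinite(qv) else False

    all_reps = activity[design.replicates]
    for eid, ref_bc, alt_bc in testable:
        rv = all_reps.reindex(ref_bc).to_numpy(dtype=float)
        av = all_reps.reindex(alt_bc).to_numpy(dtype=float)
        delta = np.nanmedian(av) - np.nanmedian(rv)
        calls[eid].direction = int(np.sign(delta)) if delta == delta else 0
        calls[eid].concordant = concordance(calls[eid].sig, design)
        calls[eid].is_emvar = calls[eid].concordant
    return [calls[eid] for eid, _, _ in testable]
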