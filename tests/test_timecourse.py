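"""TMM, expression filters, HSV transformation, clustering rules, peaks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emvarkit import synthdata, timecourse
from emvarkit.timecourse import (
    assign_clusters, bin_patterns, cpm_matrix, filter_for_clustering,
    filter_for_hsv, fuzzy_cmeans, harmonize_peaks, hsv_table, hsv_transform,
    tmm_effective_libsize, tmm_factors,
)


def tmm_oracle(counts: pd.DataFrame, ref_col) -> dict:
    """Step-by-step reimplementation of trimmed-mean-of-M-values, written
    plainly from the published definition (independent of the package's
    vectorised version)."""
    lib = {c: float(counts[c].sum()) for c in counts.columns}
    logf = {}
    for col in counts.columns:
        ms, as_, ws = [], [], []
        for g in counts.index:
            o, r = float(counts.loc[g, col]), float(counts.loc[g, ref_col])
            if o > 0 and r > 0:
                po, pr = o / lib[col], r / lib[ref_col]
                ms.append(math.log2(po / pr))
                as_.append(0.5 * math.log2(po * pr))
                ws.append((lib[col] - o) / (lib[col] * o)
                          + (lib[ref_col] - r) / (lib[ref_col] * r))
        n = len(ms)
        order_m = sorted(range(n), key=lambda i: ms[i])
        order_a = sorted(range(n), key=lambda i: as_[i])
        rank_m = {i: k + 1 for k, i in enumerate(order_m)}
        rank_a = {i: k + 1 for k, i in enumerate(order_a)}
        lo_m, hi_m = math.floor(n * 0.30) + 1, n - math.floor(n * 0.30)
        lo_a, hi_a = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += ms[i] / ws[i]
                den += 1.0 / ws[i]
        logf[col] = num / den if den else 0.0
    center = sum(logf.values()) / len(logf)
    return {c: 2 ** (v - center) for c, v in logf.items()}


class TestTMM:
    def test_identical_columns_all_factors_one(self):
        col = np.array([10, 200, 3000, 40, 500] * 10)
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_uniform_scaling_recovered_via_effective_libsize(self):
        """A column that is exactly 2x another is a pure depth change: TMM
        factor stays 1 and the effective library size carries the 2-fold."""
        rng = np.random.default_rng(12)
        a = rng.negative_binomial(5, 0.02, 300) + 1
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-8)
        eff = tmm_effective_libsize(counts)
        assert eff["b"] / eff["a"] == pytest.approx(2.0)
        norm = counts / eff
        assert np.allclose(norm["a"], norm["b"])

    def test_matches_independent_step_by_step_oracle(self):
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(rng.negative_binomial(4, 0.01, size=(200, 4)),
                              columns=list("abcd"))
        counts.iloc[:30, 2] *= 5  # plant composition bias
        ref = "a"
        got = tmm_factors(counts, ref_col=ref)
        want = tmm_oracle(counts, ref_col=ref)
        for c in counts.columns:
            assert got[c] == pytest.approx(want[c], abs=1e-8)

    def test_no_shared_genes_factor_one_with_warning(self):
        counts = pd.DataFrame({"a": [5, 0, 9, 0], "b": [0, 7, 0, 3]})
        with pytest.warns(UserWarning, match="shares no expressed genes"):
            f = tmm_factors(counts, ref_col="a")
        assert f["b"] == pytest.approx(1.0 / f["a"])  # centred, b's log factor 0


class TestExpressionFilters:
    def test_clustering_filter_boundary(self):
        # build genes with exactly 3 and 4 low-CPM samples
        counts = pd.DataFrame(np.full((4, 8), 1000), index=list("wxyz"))
        counts.iloc[1, :3] = 0   # 3 samples below: kept
        counts.iloc[2, :4] = 0   # 4 samples below: removed
        out = filter_for_clustering(counts)
        assert "x" in out.index and "y" not in out.index

    def test_planted_failing_genes_all_removed(self):
        rng = np.random.default_rng(14)
        counts = pd.DataFrame(rng.integers(500, 2000, size=(50, 6)))
        fail = rng.choice(50, 10, replace=False)
        counts.iloc[fail, :4] = 0
        out = filter_for_clustering(counts)
        assert len(out) == 40
        assert not set(fail) & set(out.index)

    def test_hsv_filter_boundary_and_any_timepoint(self):
        tpm = pd.DataFrame(
            {"t0_r1": [2.0, 2.0, 8.0], "t0_r2": [2.0, 2.0, 8.0],
             "t1_r1": [2.0, 1.4, 8.0], "t1_r2": [2.0, 1.45, 8.0]},
            index=["at_boundary", "dips", "high"])
        tp_of = {c: c.split("_")[0] for c in tpm.columns}
        out = filter_for_hsv(tpm, tp_of)
        # mean log2(TPM)=1.0 exactly is not < 1: kept
        assert "at_boundary" in out.index
        # dips to mean log2 ~ 0.51 at t1: removed
        assert "dips" not in out.index
        assert "high" in out.index


class TestHSV:
    def test_flat_profile_static(self):
        p = hsv_transform([3, 3, 3])
        assert p.S == 0 and np.isnan(p.H) and p.pattern == "static"

    def test_hand_case_1_2_4(self):
        p = hsv_transform([1, 2, 4])
        assert p.V == pytest.approx(4.0)
        assert p.S == pytest.approx(0.75)
        assert p.H == pytest.approx(20.0)

    def test_monotone_up_sign_positive(self):
        prof = synthdata.archetype_profile("up", 4)
        p = hsv_transform(prof)
        assert prof[1] > prof[0]  # sign term +1 by construction
        assert p.pattern == "dynamic"

    def test_scale_invariance_of_h_and_s(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            c = rng.uniform(0.5, 8.0, size=5)
            p1 = hsv_transform(c)
            p2 = hsv_transform(3.7 * c)
            if p1.pattern == "dynamic":
                assert p2.H == pytest.approx(p1.H)
            assert p2.S == pytest.approx(p1.S)
            assert p2.V == pytest.approx(3.7 * p1.V)

    @given(st.lists(st.floats(min_value=0.0, max_value=100.0),
                    min_size=3, max_size=8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_s_in_unit_interval_and_never_crashes(self, c):
        p = hsv_transform(c)
        if not np.isnan(p.S):
            assert 0.0 <= p.S <= 1.0
        if not np.isnan(p.H):
            assert 0.0 <= p.H < 360.0

    def test_all_zero_profile_flagged_undefined(self):
        p = hsv_transform([0, 0, 0])
        assert p.pattern == "undefined" and np.isnan(p.H)

    def test_static_onset_flag(self):
        p = hsv_transform([2, 2, 5])
        assert p.pattern == "static-onset" and np.isnan(p.H)

    def test_fewer_than_three_timepoints_rejected(self):
        with pytest.raises(ValueError):
            hsv_transform([1, 2])

    def test_rank_scaling_order_preserving_with_extremes(self):
        profiles = pd.DataFrame(
            np.random.default_rng(16).uniform(1, 9, size=(30, 4)))
        profiles.index = [f"g{i}" for i in range(30)]
        tab = hsv_table(profiles)
        for col in ("V", "S"):
            raw, scaled = tab[f"{col}_raw"], tab[f"{col}_rank"]
            ok = raw.notna()
            assert scaled[ok].min() == pytest.approx(0.0)
            assert scaled[ok].max() == pytest.approx(1.0)
            order_raw = raw[ok].sort_values().index
            order_scaled = scaled[ok].sort_values().index
            assert list(order_raw) == list(order_scaled)


class TestBinPatterns:
    def _tab(self, h, pattern="dynamic"):
        return pd.DataFrame({"H": [h], "S_raw": [0.5], "V_raw": [1.0],
                             "pattern": [pattern]}, index=["g"])

    def test_sector_arithmetic(self):
        assert bin_patterns(self._tab(20.0), n_bins=6)["g"] == "sector_0"

    def test_wrap_boundary_last_sector(self):
        assert bin_patterns(self._tab(359.9), n_bins=6)["g"] == "sector_5"

    def test_static_keeps_flag(self):
        assert bin_patterns(self._tab(np.nan, "static"))["g"] == "static"

    def test_up_and_down_archetypes_land_in_disjoint_sectors(self):
        up = hsv_transform(synthdata.archetype_profile("up", 4))
        down = hsv_transform(synthdata.archetype_profile("down", 4))
        width = 60.0
        assert int(up.H // width) != int(down.H // width)


class TestAssignClusters:
    def _reps(self, per_rep, n_clusters=5):
        """One membership table per replicate; cluster 0 takes the given
        membership, the remainder spread evenly over the other clusters."""
        reps = []
        for v in per_rep:
            row = {0: [v]}
            row.update({k: [(1 - v) / (n_clusters - 1)]
                        for k in range(1, n_clusters)})
            reps.append(pd.DataFrame(row, index=["g"]))
        return reps

    def test_both_thresholds_met_assigned(self):
        reps = self._reps((0.25, 0.30, 0.40))  # avg 0.3167 > 0.3, all > 0.2
        out = assign_clusters(reps)
        assert out[0].cluster == 0

    def test_one_replicate_below_point_two_unassigned(self):
        reps = self._reps((0.10, 0.45, 0.50))
        out = assign_clusters(reps)
        assert out[0].cluster == -1

    def test_average_exactly_point_three_unassigned(self):
        reps = self._reps((0.30, 0.30, 0.30))
        out = assign_clusters(reps)
        assert out[0].membership_avg == pytest.approx(0.30)
        assert out[0].cluster == -1

    def test_never_assigns_best_membership_below_threshold(self):
        rng = np.random.default_rng(17)
        reps = []
        for _ in range(3):
            m = rng.dirichlet(np.ones(5), size=20)
            reps.append(pd.DataFrame(m, index=[f"g{i}" for i in range(20)]))
        for rec in assign_clusters(reps):
            if rec.cluster != -1:
                assert rec.membership_avg > 0.3

    def test_membership_rows_not_summing_warn(self):
        bad = [pd.DataFrame({0: [0.2], 1: [0.2]}, index=["g"])]
        with pytest.warns(UserWarning, match="sum to 1"):
            assign_clusters(bad)


class TestFuzzyCMeans:
    def test_archetype_recovery_above_chance(self):
        """Clustering scaled profiles of four archetypes recovers the truth
        with adjusted Rand well above chance, across 5 seeds."""
        from sklearn.metrics import adjusted_rand_score
        aris = []
        for seed in range(5):
            counts, truth = synthdata.simulate_timecourse(
                n_genes=120, n_timepoints=4, n_reps=3, seed=seed)
            prof = np.log2(cpm_matrix(counts) + 1.0)
            tp = synthdata.timepoint_map(prof.columns)
            by_tp = prof.T.groupby(pd.Series(tp)).mean().T
            z = by_tp.sub(by_tp.mean(axis=1), axis=0)
            z = z.div(z.std(axis=1).replace(0, 1.0), axis=0)
            _, u = fuzzy_cmeans(z.to_numpy(), 4, seed=seed)
            labels = u.argmax(axis=1)
            aris.append(adjusted_rand_score(truth.to_numpy(), labels))
        assert np.mean(aris) > 0.3

    def test_memberships_sum_to_one(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=(40, 3))
        _, u = fuzzy_cmeans(x, 3, seed=1)
        assert np.allclose(u.sum(axis=1), 1.0)


class TestHarmonizePeaks:
    def test_single_peak_centering(self):
        pk = pd.DataFrame({"chrom": ["chr1"], "start": [10_200], "end": [10_800],
                           "summit": [10_500], "score": [5.0]})
        out = harmonize_peaks(pk)
        assert out.iloc[0].tolist() == ["chr1", 10_000, 11_000]

    def test_highest_peak_summit_wins(self):
        pk = pd.DataFrame({"chrom": ["chr1", "chr1"],
                           "start": [10_000, 10_400], "end": [10_600, 11_000],
                           "summit": [10_300, 10_700], "score": [5.0, 9.0]})
        out = harmonize_peaks(pk)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 10_700 - 500

    def test_disjoint_peaks_count_conserved_and_width_fixed(self):
        pk = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [1_000, 9_000, 4_000],
            "end": [2_000, 10_000, 5_000],
            "summit": [1_500, 9_500, 4_500],
            "score": [3.0, 4.0, 5.0],
        })
        out = harmonize_peaks(pk)
        assert len(out) == 3
        assert ((out["end"] - out["start"]) == 1000).all()

    def test_missing_summit_falls_back_to_midpoint(self):
        pk = pd.DataFrame({"chrom": ["chr1"], "start": [1_000], "end": [2_000],
                           "summit": [np.nan], "score": [1.0]})
        with pytest.warns(UserWarning, match="midpoint"):
            out = harmonize_peaks(pk)
        assert out.iloc[0]["start"] == 1_500 - 500
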