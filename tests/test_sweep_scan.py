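import math

import numpy as np
import pytest

import sweepscan as ss
from sweepscan import sweep_scan as sw
from sweepscan.genotype_model import Window, breed_frequencies, make_windows
from sweepscan.sweep_scan import (
    CandidateRegion,
    NullLengthDistribution,
    marginal_p,
    merge_to_regions,
    per_snp_di,
    region_significance,
    tail_windows,
)

from conftest import build_panel, random_panel
from oracles import bh_stepup, interval_union, wc_theta_scalar


def window_of(panel, lo, hi):
    return Window("chr1", 0, 10 * hi, np.arange(lo, hi))


class TestRelativeHeterozygosity:
    def test_formula(self):
        # breed b0: 10 polymorphic loci; breed b1: 30
        geno = np.zeros((4, 40), dtype=np.int8)
        geno[0, :10] = 1          # b0 segregates at loci 0-9
        geno[2, :30] = 1          # b1 segregates at loci 0-29
        panel = build_panel(geno, ["b0", "b0", "b1", "b1"])
        freqs = breed_frequencies(panel)
        w = window_of(panel, 0, 40)
        assert ss.relative_heterozygosity(freqs, w, "b0", "b1") == pytest.approx(0.25)

    def test_symmetry_at_equal_counts(self):
        geno = np.zeros((4, 10), dtype=np.int8)
        geno[0, :5] = 1
        geno[2, 5:] = 1
        panel = build_panel(geno, ["b0", "b0", "b1", "b1"])
        freqs = breed_frequencies(panel)
        w = window_of(panel, 0, 10)
        assert ss.relative_heterozygosity(freqs, w, "b0", "b1") == 0.5

    def test_complement_identity(self):
        geno = np.zeros((4, 10), dtype=np.int8)
        geno[2, :7] = 1
        panel = build_panel(geno, ["b0", "b0", "b1", "b1"])
        freqs = breed_frequencies(panel)
        w = window_of(panel, 0, 10)
        t01 = ss.relative_heterozygosity(freqs, w, "b0", "b1")
        t10 = ss.relative_heterozygosity(freqs, w, "b1", "b0")
        assert (t01, t10) == (0.0, 1.0)

    def test_undefined_when_both_monomorphic(self):
        panel = build_panel(np.zeros((4, 10), dtype=np.int8),
                            ["b0", "b0", "b1", "b1"])
        freqs = breed_frequencies(panel)
        w = window_of(panel, 0, 10)
        assert math.isnan(ss.relative_heterozygosity(freqs, w, "b0", "b1"))


def si_oracle(freqs, windows, breeds):
    """Independent loop implementation of the S_i scan (autosomes only)."""
    poly = (freqs.freq_b > 0) & (freqs.freq_b < 1)
    n_b = len(breeds)
    h = np.array([[poly[k, w.snp_indices].sum() for w in windows]
                  for k in range(n_b)])
    H = poly.sum(axis=1)
    values = np.zeros((n_b, len(windows)))
    for i in range(n_b):
        for j in range(n_b):
            if i == j:
                continue
            thetas = []
            for w in range(len(windows)):
                tot = h[i, w] + h[j, w]
                thetas.append(h[i, w] / tot if tot else np.nan)
            thetas = np.array(thetas)
            e = H[i] / (H[i] + H[j])
            sd = np.nanstd(thetas, ddof=1)
            if not sd > 0:
                continue
            for w in range(len(windows)):
                if not np.isnan(thetas[w]):
                    values[i, w] += (thetas[w] - e) / sd
    return values


def di_oracle(freqs, breeds):
    """Independent loop implementation of per-SNP d_i."""
    n_b = len(breeds)
    n_l = freqs.freq_b.shape[1]
    d = np.zeros((n_b, n_l))
    for i in range(n_b):
        for j in range(n_b):
            if j <= i:
                continue
            fst = np.array(
                [wc_theta_scalar([freqs.freq_b[i, l], freqs.freq_b[j, l]],
                                 [freqs.n_called[i, l], freqs.n_called[j, l]])
                 for l in range(n_l)]
            )
            e = np.nanmean(fst)
            sd = np.nanstd(fst, ddof=1)
            if not sd > 0:
                continue
            z = (fst - e) / sd
            for l in range(n_l):
                if not np.isnan(z[l]):
                    d[i, l] += z[l]
                    d[j, l] += z[l]
    return d


class TestScans:
    def test_s_i_matches_hand_implementation(self):
        rng = np.random.default_rng(17)
        panel = random_panel(rng, n_breeds=3, n_per_breed=8, n_loci=120, n_chroms=1)
        freqs = breed_frequencies(panel)
        windows = make_windows(panel.loci, 200_000, 50_000, min_snps=2)
        assert len(windows) > 5
        tracks, _ = ss.s_i_scan(freqs, windows)
        expect = si_oracle(freqs, windows, freqs.breeds)
        for k, b in enumerate(freqs.breeds):
            np.testing.assert_allclose(tracks[b].values, expect[k], atol=1e-10)

    def test_d_i_matches_hand_implementation(self):
        rng = np.random.default_rng(19)
        panel = random_panel(rng, n_breeds=3, n_per_breed=8, n_loci=60, n_chroms=1)
        freqs = breed_frequencies(panel)
        d, _ = per_snp_di(freqs)
        np.testing.assert_allclose(d, di_oracle(freqs, freqs.breeds), atol=1e-10)

    def test_window_d_i_is_mean_of_member_snps(self):
        rng = np.random.default_rng(23)
        panel = random_panel(rng, n_breeds=3, n_per_breed=8, n_loci=60, n_chroms=1)
        freqs = breed_frequencies(panel)
        windows = make_windows(panel.loci, 200_000, 200_000, min_snps=2)
        tracks, _ = ss.d_i_scan(freqs, windows)
        d, _ = per_snp_di(freqs)
        for k, b in enumerate(freqs.breeds):
            for w, win in enumerate(windows):
                assert tracks[b].values[w] == pytest.approx(
                    d[k, win.snp_indices].mean()
                )

    def test_theta_complement_two_breeds_move_oppositely(self):
        rng = np.random.default_rng(29)
        panel = random_panel(rng, n_breeds=2, n_per_breed=10, n_loci=100, n_chroms=1)
        freqs = breed_frequencies(panel)
        windows = make_windows(panel.loci, 200_000, 50_000, min_snps=2)
        tracks, _ = ss.s_i_scan(freqs, windows)
        np.testing.assert_allclose(
            tracks["b0"].values, -tracks["b1"].values, atol=1e-10
        )

    def test_standardized_fst_mean_zero_sd_one(self):
        rng = np.random.default_rng(31)
        panel = random_panel(rng, n_breeds=3, n_per_breed=8, n_loci=80, n_chroms=1)
        freqs = breed_frequencies(panel)
        _, moments = per_snp_di(freqs)
        m = moments[0]
        for i in range(3):
            for j in range(i + 1, 3):
                fst = ss.fst_pair(freqs, m.breeds[i], m.breeds[j])
                z = (fst - m.e_fst[i, j]) / m.sd_fst[i, j]
                assert np.nanmean(z) == pytest.approx(0.0, abs=1e-12)
                assert np.nanstd(z, ddof=1) == pytest.approx(1.0)

    def test_homozygous_window_is_breed_minimum(self):
        rng = np.random.default_rng(37)
        panel = random_panel(rng, n_breeds=3, n_per_breed=8, n_loci=200, n_chroms=1)
        # wipe all variation in b0 over one window's span
        span = (panel.loci["pos"] >= 400_000) & (panel.loci["pos"] < 600_000)
        rows = panel.breed_mask("b0")
        panel.genotypes[np.ix_(rows, span.to_numpy())] = 0
        freqs = breed_frequencies(panel)
        windows = make_windows(panel.loci, 200_000, 50_000, min_snps=2)
        tracks, _ = ss.s_i_scan(freqs, windows)
        k = int(np.argmin(tracks["b0"].values))
        win = tracks["b0"].windows[k]
        assert win.start >= 250_000 and win.end <= 750_000


class TestTailWindows:
    @staticmethod
    def track(values, statistic=sw.S_I):
        wins = [Window("chr1", 1000 * i, 1000 * i + 1000, np.array([i]))
                for i in range(len(values))]
        return sw.WindowStatTrack("b0", statistic, wins,
                                  np.asarray(values, dtype=float),
                                  np.ones(len(values), dtype=np.int64))

    def test_count_arithmetic(self):
        rng = np.random.default_rng(41)
        flagged = tail_windows(self.track(rng.normal(size=1000)))
        assert len(flagged) == 10

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(43)
        vals = rng.normal(size=500)
        flagged = tail_windows(self.track(vals), tail_frac=0.02)
        expect = set(np.argsort(vals)[:10])
        assert {w.snp_indices[0] for w in flagged} == expect

    def test_high_tail_for_di(self):
        rng = np.random.default_rng(47)
        vals = rng.normal(size=500)
        flagged = tail_windows(self.track(vals, sw.D_I), tail_frac=0.02)
        expect = set(np.argsort(vals)[-10:])
        assert {w.snp_indices[0] for w in flagged} == expect

    def test_all_tied_all_flagged(self, caplog):
        with caplog.at_level("WARNING", logger="sweepscan"):
            flagged = tail_windows(self.track([1.0] * 200))
        assert len(flagged) == 200

    def test_too_few_windows_fatal(self):
        with pytest.raises(ValueError, match="too few windows"):
            tail_windows(self.track([1.0] * 50))


class TestMergeToRegions:
    @staticmethod
    def win(start, end, chrom="chr1"):
        return Window(chrom, start, end, np.array([0]))

    def test_overlapping_windows_union(self):
        regions = merge_to_regions(
            [self.win(0, 150_000), self.win(25_000, 175_000)], "b0", sw.S_I
        )
        assert [(r.start, r.end, r.n_windows) for r in regions] == [(0, 175_000, 2)]

    def test_distant_windows_stay_separate(self):
        regions = merge_to_regions(
            [self.win(0, 150_000), self.win(1_000_000, 1_150_000)], "b0", sw.S_I
        )
        assert len(regions) == 2

    def test_single_window_region_length(self):
        regions = merge_to_regions([self.win(25_000, 175_000)], "b0", sw.S_I)
        assert regions[0].length_bp == 150_000

    def test_matches_interval_union_oracle(self):
        rng = np.random.default_rng(53)
        starts = rng.choice(np.arange(0, 5_000_000, 25_000), size=40, replace=False)
        wins = [self.win(int(s), int(s) + 150_000) for s in starts]
        regions = merge_to_regions(wins, "b0", sw.S_I)
        expect = interval_union([(w.start, w.end) for w in wins])
        assert [(r.start, r.end) for r in regions] == expect


class TestRegionSignificance:
    def test_marginal_p_add_one_rule(self):
        assert marginal_p(500_000, np.array([100, 200, 600, 800]) * 1000) == \
            pytest.approx(3 / 5)

    def test_extreme_region_hits_floor(self):
        null = np.arange(1, 1000) * 1000
        assert marginal_p(10**9, null) == pytest.approx(1 / 1000)

    def test_plain_proportion_flag(self):
        assert marginal_p(10**9, np.array([1, 2, 3]), add_one=False) == 0.0

    def test_ties_count_as_not_longer(self):
        assert marginal_p(500, np.array([500, 500, 600])) == pytest.approx(2 / 4)

    def test_bh_matches_hand_stepup(self):
        # craft per-breed nulls so marginal p = .001, .02, .03, .04
        regions = []
        null = {}
        for k, p in enumerate([0.001, 0.02, 0.03, 0.04]):
            breed = f"b{k}"
            n = 999
            longer = int(round(p * 1000)) - 1
            null[(breed, sw.S_I)] = np.array([200] * longer + [50] * (n - longer))
            regions.append(CandidateRegion(breed, sw.S_I, "chr1", 0, 100, 1))
        out = region_significance(regions, NullLengthDistribution(null), alpha=0.05)
        pvals = [r.marginal_p for r in out]
        np.testing.assert_allclose(pvals, [0.001, 0.02, 0.03, 0.04])
        assert [r.significant for r in out] == bh_stepup(pvals, 0.05)
        assert all(r.significant for r in out)

    def test_missing_breed_fatal(self):
        regions = [CandidateRegion("bX", sw.S_I, "chr1", 0, 100, 1)]
        with pytest.raises(KeyError):
            region_significance(regions, NullLengthDistribution({}))


class TestDeterminism:
    def test_identical_inputs_identical_regions(self):
        rng = np.random.default_rng(59)
        panel = random_panel(rng, n_breeds=3, n_per_breed=8, n_loci=300, n_chroms=1)
        freqs = breed_frequencies(panel)
        windows = make_windows(panel.loci, 150_000, 25_000, min_snps=2)
        out = []
        for _ in range(2):
            regions = ss.scan_regions(freqs, windows, tail_frac=0.05)
            out.append(sw.regions_to_frame(regions).to_csv(index=False))
        assert out[0] == out[1]
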