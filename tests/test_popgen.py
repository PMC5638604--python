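"""Pooled diversity and F_ST estimators, window summaries, tail thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paradapt.io_core import AnalysisConfig, SiteCounts
from paradapt.popgen import (
    FilterResult,
    SnpRecord,
    WindowStat,
    filter_site,
    site_heterozygosity,
    snp_fst,
    window_fst,
    window_pi,
    window_tails,
)


def _site(pool1, pool2):
    return SiteCounts("scf1", 1, "A", (tuple(pool1), tuple(pool2)))


class TestSiteHeterozygosity:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((10, 10), (20 / 19) * 0.5),
            ((20, 0), 0.0),
            ((15, 5), (20 / 19) * (1 - 0.625)),
        ],
    )
    def test_known_values(self, counts, expected):
        assert site_heterozygosity(counts) == pytest.approx(expected, abs=1e-12)

    def test_coverage_below_two_is_an_error(self):
        with pytest.raises(ValueError):
            site_heterozygosity((1, 0))

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 500), min_size=2, max_size=4).filter(lambda c: sum(c) >= 2))
    def test_bounds_and_zero_iff_monomorphic(self, counts):
        c = sum(counts)
        k = len(counts)
        h = site_heterozygosity(counts)
        assert 0.0 <= h <= (c / (c - 1)) * (1 - 1 / k) + 1e-12
        monomorphic = sum(1 for x in counts if x > 0) <= 1
        assert (h == 0.0) == monomorphic

    def test_unbiased_for_true_heterozygosity(self):
        # binomial read sampling at 60x: mean corrected heterozygosity
        # matches 2p(1-p) within 3 standard errors over 10,000 replicates
        rng = np.random.default_rng(42)
        for p in (0.1, 0.3, 0.5):
            d = rng.binomial(60, p, size=10_000)
            h = np.array([site_heterozygosity((60 - x, x)) for x in d])
            se = h.std(ddof=1) / math.sqrt(len(h))
            assert abs(h.mean() - 2 * p * (1 - p)) < 3 * se


class TestSnpFst:
    def test_identical_pools_near_zero(self):
        # the c/(c-1) correction differs between the 20x pools and the 40x
        # pooled total, so identical pools sit slightly below zero; the
        # value matches the closed form and vanishes as coverage grows
        pi_w = (20 / 19) * 0.5
        pi_t = (40 / 39) * 0.5
        assert snp_fst((10, 10), (10, 10)) == pytest.approx((pi_t - pi_w) / pi_t)
        assert snp_fst((5000, 5000), (5000, 5000)) == pytest.approx(0.0, abs=1e-4)

    def test_fixed_difference_gives_one(self):
        assert snp_fst((20, 0), (0, 20)) == pytest.approx(1.0)

    def test_worked_example(self):
        pi_w = (20 / 19) * (1 - 0.625)
        pi_t = (40 / 39) * 0.5
        assert snp_fst((15, 5), (5, 15)) == pytest.approx((pi_t - pi_w) / pi_t)
        assert snp_fst((15, 5), (5, 15)) == pytest.approx(0.23026, abs=1e-5)

    def test_monomorphic_combined_site_is_undefined(self):
        assert snp_fst((20, 0), (30, 0)) is None

    def test_converges_to_true_frequency_fst_at_high_coverage(self):
        # scaling counts x1000 approaches the infinite-coverage value
        p1, p2 = 0.75, 0.25
        pi_w = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
        pbar = (p1 + p2) / 2
        pi_t = 2 * pbar * (1 - pbar)
        truth = (pi_t - pi_w) / pi_t
        big = snp_fst((15_000, 5_000), (5_000, 15_000))
        assert big == pytest.approx(truth, abs=1e-3)


class TestFilterSite:
    def test_two_alternate_observations_make_a_snp(self, default_cfg):
        res = filter_site(_site((18, 0, 2, 0, 0, 0), (20, 0, 0, 0, 0, 0)), default_cfg)
        assert res.status == "snp"
        assert (res.snp.major, res.snp.minor) == ("A", "C")
        assert res.snp.counts == ((18, 2), (20, 0))

    def test_single_alternate_observation_rejected(self, default_cfg):
        res = filter_site(_site((19, 0, 1, 0, 0, 0), (20, 0, 0, 0, 0, 0)), default_cfg)
        assert (res.status, res.reason) == ("rejected", "min_alt")

    def test_triallelic_rejected(self, default_cfg):
        res = filter_site(_site((10, 5, 5, 0, 0, 0), (20, 0, 0, 0, 0, 0)), default_cfg)
        assert (res.status, res.reason) == ("rejected", "triallelic")

    def test_low_coverage_pool_rejected(self, default_cfg):
        res = filter_site(_site((15, 4, 0, 0, 0, 0), (20, 0, 0, 0, 0, 0)), default_cfg)
        assert (res.status, res.reason) == ("rejected", "coverage")

    def test_n_and_del_do_not_count_toward_coverage(self, default_cfg):
        # 19 base calls + 1 N: coverage is 19, below the minimum
        res = filter_site(_site((19, 0, 0, 0, 1, 0), (20, 0, 0, 0, 0, 0)), default_cfg)
        assert (res.status, res.reason) == ("rejected", "coverage")

    def test_monomorphic_covered_passes_through(self, default_cfg):
        res = filter_site(_site((25, 0, 0, 0, 0, 0), (30, 0, 0, 0, 0, 0)), default_cfg)
        assert res.status == "monomorphic_covered"


def _mono(n):
    return [FilterResult("monomorphic_covered")] * n


class TestWindowPi:
    def test_all_monomorphic_gives_zero(self, default_cfg):
        assert window_pi(_mono(1000), 1000, default_cfg) == (0.0, 0.0)

    def test_covered_fraction_below_half_is_undefined(self, default_cfg):
        assert window_pi(_mono(499), 1000, default_cfg) is None

    def test_single_snp_window_value(self, default_cfg):
        snp = SnpRecord("scf1", 5, "A", "C", ((15, 5), (15, 5)))
        results = _mono(999) + [FilterResult("snp", snp=snp)]
        pi = window_pi(results, 1000, default_cfg)
        assert pi[0] == pytest.approx(0.00039474, abs=1e-8)

    def test_denominator_is_covered_sites_not_window_length(self, default_cfg):
        snp = SnpRecord("scf1", 5, "A", "C", ((15, 5), (15, 5)))
        results = _mono(599) + [FilterResult("snp", snp=snp)]
        pi = window_pi(results, 1000, default_cfg)
        assert pi[0] == pytest.approx(site_heterozygosity((15, 5)) / 600)


class TestWindowFst:
    def test_mean_of_snp_fst(self):
        snps = [
            SnpRecord("s", 1, "A", "C", ((1, 1), (1, 1)), fst=0.1),
            SnpRecord("s", 2, "A", "C", ((1, 1), (1, 1)), fst=0.3),
        ]
        assert window_fst(snps) == pytest.approx(0.2)

    def test_snp_free_window_contributes_zero(self):
        assert window_fst([]) == 0.0


def _windows(fsts):
    return [
        WindowStat("s", 1000 * i + 1, 1000 * (i + 1), 1000, 1.0, (0.0, 0.0), f)
        for i, f in enumerate(fsts)
    ]


class TestWindowTails:
    def test_rank_constructed_distribution(self):
        wins = _windows([(i + 1) / 1000 for i in range(1000)])
        tails = window_tails(wins, (0.01, 0.025, 0.05))
        assert tails[0.05]["threshold"] == pytest.approx(0.951)
        assert tails[0.05]["n_flagged"] == 50
        assert tails[0.01]["n_flagged"] == 10
        assert tails[0.05]["mean_fst"] == pytest.approx(np.mean(np.arange(951, 1001) / 1000))

    def test_all_equal_windows_all_flagged(self):
        wins = _windows([0.2] * 40)
        tails = window_tails(wins, (0.05,))
        assert tails[0.05]["n_flagged"] == 40  # ties at the threshold kept

    def test_two_windows_half_fraction_flags_larger(self):
        wins = _windows([0.1, 0.4])
        tails = window_tails(wins, (0.5,))
        assert tails[0.5]["n_flagged"] == 1
        assert wins[1].tail_flags[0.5] and not wins[0].tail_flags[0.5]

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            window_tails([], (0.05,))


def test_genome_mean_pi_consistency(small_popgen_sim, default_cfg):
    """With fully covered windows, the mean of window pi equals the summed
    site heterozygosity over the summed covered-site count."""
    from paradapt.popgen import window_stats

    lengths = {s: len(seq) for s, seq in small_popgen_sim.genome.items()}
    total_het = 0.0
    total_cov = 0
    weighted = 0.0
    for stat, snps in window_stats(iter(small_popgen_sim.sites), lengths, default_cfg):
        assert stat.defined  # simulated coverage is far above the minimum
        total_cov += stat.n_sites_covered
        weighted += stat.pi[0] * stat.n_sites_covered
        total_het += sum(site_heterozygosity(s.counts[0]) for s in snps)
    assert weighted == pytest.approx(total_het)
    assert total_cov > 0
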