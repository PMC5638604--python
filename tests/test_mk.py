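"""MK count tables, Fisher/alpha/DoS, adaptive calls, sex bias, correlations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paradapt.io_core import AnalysisConfig, SiteCounts
from paradapt.mk import (
    MKCounts,
    SEX_BIAS_CLASSES,
    alpha_correlation,
    build_mk_table,
    call_adaptive,
    classify_sex_bias,
    enrichment_chi2,
    evaluate_gene,
    mk_filter_snps,
    mk_test,
    mk_testable,
)


class TestBuildMkTable:
    def test_fixed_nonsynonymous_difference(self):
        counts = build_mk_table("ATG", "ATG", "ATA")  # Met vs Ile
        assert (counts.Dn, counts.Ds, counts.Pn, counts.Ps) == (1, 0, 0, 0)

    def test_synonymous_polymorphism(self):
        counts = build_mk_table("CTG", "CTA", "CTG")  # Leu/Leu
        assert (counts.Dn, counts.Ds, counts.Pn, counts.Ps) == (0, 0, 0, 1)

    def test_gap_and_ambiguous_codons_skipped(self):
        counts = build_mk_table("ATG" + "A-G", "ATG" + "AAG", "ATA" + "AAG")
        assert (counts.Dn, counts.Ds, counts.Pn, counts.Ps) == (1, 0, 0, 0)

    def test_planted_counts_recovered_exactly(self):
        rng = np.random.default_rng(3)
        from paradapt.synthetic_data import mk_alignment_from_counts

        planted = MKCounts(Dn=2, Ds=1, Pn=1, Ps=3)
        f1, f2, og = mk_alignment_from_counts(planted, rng, n_codons=30)
        got = build_mk_table(f1, f2, og)
        assert (got.Dn, got.Ds, got.Pn, got.Ps) == (2, 1, 1, 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_mk_table("ATGATG", "ATG", "ATG")
        with pytest.raises(ValueError):
            build_mk_table("ATGA", "ATGA", "ATGA")


class TestMkFilter:
    def _site(self, pool1, pool2):
        return SiteCounts("s", 1, "A", (tuple(pool1), tuple(pool2)))

    def test_minor_three_accepted(self, default_cfg):
        site = self._site((22, 0, 3, 0, 0, 0), (25, 0, 0, 0, 0, 0))
        assert mk_filter_snps(site, default_cfg)

    def test_minor_two_rejected(self, default_cfg):
        site = self._site((23, 0, 2, 0, 0, 0), (25, 0, 0, 0, 0, 0))
        assert not mk_filter_snps(site, default_cfg)

    def test_low_coverage_rejected(self, default_cfg):
        site = self._site((16, 0, 3, 0, 0, 0), (25, 0, 0, 0, 0, 0))
        assert not mk_filter_snps(site, default_cfg)


class TestTestability:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((2, 1, 1, 3), True),
            ((0, 3, 0, 5), False),  # no nonsynonymous variants anywhere
            ((2, 0, 0, 3), True),  # marginals all non-empty
            ((0, 0, 1, 1), False),  # no divergence
        ],
    )
    def test_four_category_rule(self, counts, expected):
        assert mk_testable(MKCounts(*counts)) is expected

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(0, 5)] * 4))
    def test_rule_equals_marginal_definition(self, counts):
        c = MKCounts(*counts)
        expected = (
            c.Pn + c.Ps >= 1
            and c.Dn + c.Ds >= 1
            and c.Ps + c.Ds >= 1
            and c.Pn + c.Dn >= 1
        )
        assert mk_testable(c) is expected


def enum_fisher_p(a, b, c, d):
    """Independent minimal-likelihood two-sided Fisher oracle."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {x: math.comb(r1, x) * math.comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    cutoff = pmf[a] * (1 + 1e-7)
    return min(1.0, sum(p for p in pmf.values() if p <= cutoff))


class TestMkTest:
    def test_neutral_identity(self):
        p, alpha, dos = mk_test(MKCounts(10, 5, 10, 5))
        assert p == pytest.approx(1.0)
        assert alpha == pytest.approx(0.0)
        assert dos == pytest.approx(0.0)

    def test_worked_example(self):
        p, alpha, dos = mk_test(MKCounts(10, 5, 2, 8))
        assert alpha == pytest.approx(0.875)
        assert dos == pytest.approx(10 / 15 - 2 / 10)
        assert p == pytest.approx(enum_fisher_p(10, 5, 2, 8), abs=1e-12)

    def test_fisher_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            dn, ds, pn, ps = (int(x) for x in rng.integers(0, 11, size=4))
            if not mk_testable(MKCounts(dn, ds, pn, ps)):
                continue
            p, _, _ = mk_test(MKCounts(dn, ds, pn, ps))
            assert p == pytest.approx(enum_fisher_p(dn, ds, pn, ps), abs=1e-12)

    def test_alpha_undefined_when_dn_or_ps_zero(self):
        assert mk_test(MKCounts(0, 5, 2, 8))[1] is None
        assert mk_test(MKCounts(10, 5, 2, 0))[1] is None

    def test_dos_undefined_on_empty_row(self):
        assert mk_test(MKCounts(0, 0, 2, 8))[2] is None


class TestAdaptiveCall:
    def _record(self, p, alpha, dos):
        rec = evaluate_gene("g", MKCounts(1, 1, 1, 1))
        rec.fisher_p, rec.alpha, rec.dos = p, alpha, dos
        return rec

    @pytest.mark.parametrize(
        "p, alpha, dos, expected",
        [
            (0.01, 0.5, 0.2, True),
            (0.01, -0.4, -0.1, False),  # significant but purifying direction
            (0.06, 0.9, 0.5, False),
            (0.01, None, 0.5, False),
        ],
    )
    def test_joint_criterion(self, p, alpha, dos, expected):
        assert call_adaptive(self._record(p, alpha, dos)) is expected

    def test_adaptive_count_monotone_in_p_threshold(self):
        rng = np.random.default_rng(12)
        recs = [
            evaluate_gene(f"g{i}", MKCounts(*rng.integers(1, 20, size=4)))
            for i in range(200)
        ]
        counts = [
            sum(call_adaptive(r, p_threshold=t) for r in recs if r.testable)
            for t in (0.2, 0.1, 0.05, 0.01)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSexBias:
    @pytest.mark.parametrize(
        "male, female, expected",
        [
            (5, 2, "male_biased"),
            (5, 0.1, "male_specific"),
            (1.5, 1.0, "unbiased"),
            (0.5, 0.6, "not_expressed"),
            (0.1, 4.0, "female_specific"),
            (2.0, 6.0, "female_biased"),
            (2.0, 4.0, "female_biased"),  # exactly two-fold counts as biased
        ],
    )
    def test_classes(self, male, female, expected):
        assert classify_sex_bias(male, female) == expected

    @settings(max_examples=300, derandomize=True)
    @given(st.floats(0, 50, allow_nan=False), st.floats(0, 50, allow_nan=False))
    def test_total_partition(self, male, female):
        assert classify_sex_bias(male, female) in SEX_BIAS_CLASSES


class TestEnrichment:
    def test_identical_proportions_null(self):
        stat, p = enrichment_chi2([[30, 70], [30, 70]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        stat, p = enrichment_chi2([[30, 70], [10, 90]])
        assert stat == pytest.approx(12.5)
        assert p == pytest.approx(4.07e-4, rel=1e-2)

    def test_transpose_symmetry(self):
        a = enrichment_chi2([[30, 70], [10, 90]])
        b = enrichment_chi2([[30, 10], [70, 90]])
        assert a[0] == pytest.approx(b[0])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            enrichment_chi2([[0, 0], [10, 90]])


class TestAlphaCorrelation:
    def test_concordant_and_reversed_ranks(self):
        pairs = [(0.1, 0.2), (0.3, 0.5), (0.7, 0.9), (0.8, 0.95)]
        rho, _ = alpha_correlation(pairs)
        assert rho == pytest.approx(1.0)
        rho_rev, _ = alpha_correlation([(a, -b) for a, b in pairs])
        assert rho_rev == pytest.approx(-1.0)

    def test_matches_explicit_rank_computation(self):
        rng = np.random.default_rng(5)
        x = rng.random(10)
        y = rng.random(10)
        rho, _ = alpha_correlation(list(zip(x, y)))
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            alpha_correlation([(0.1, 0.2), (0.3, 0.4)])
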