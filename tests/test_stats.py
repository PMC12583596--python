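"""Cohort statistics: exact tests, telomere binning, permutation enrichment."""

import math

import numpy as np
import pytest

from dnsvkit.genome import GenomeMap, grch38
from dnsvkit.stats import (
    binom_two_tailed,
    class_fractions,
    density_ratio,
    detectability_class,
    dnsv_rate,
    fisher_2x2,
    ks_two_sample,
    permutation_enrichment,
    subtelomeric_ratio,
    telomere_binning,
)


def binom_oracle(k, n, p0):
    """Direct enumeration of the two-tailed exact binomial p-value."""
    pmf = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    ref = pmf[k] * (1 + 1e-9)
    return sum(p for p in pmf if p <= ref)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumeration over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_p(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    obs = table_p(a) * (1 + 1e-9)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(table_p(x) for x in range(lo, hi + 1) if table_p(x) <= obs)


class TestBinomTwoTailed:
    def test_timing_test_headline_value(self):
        assert binom_two_tailed(35, 41, 0.5) == pytest.approx(4.87e-06, rel=1e-3)

    def test_central_value_is_one(self):
        assert binom_two_tailed(5, 10, 0.5) == pytest.approx(1.0)

    def test_extreme_closed_form(self):
        assert binom_two_tailed(0, 10, 0.5) == pytest.approx(2 * 2**-10)

    @pytest.mark.parametrize("n", [1, 5, 12, 20])
    def test_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.choice([0.3, 0.5, 0.7]))
            assert binom_two_tailed(k, n, p0) == pytest.approx(
                binom_oracle(k, n, p0), rel=1e-6
            )

    def test_symmetry_at_half(self):
        for n in (7, 14):
            for k in range(n + 1):
                assert binom_two_tailed(k, n, 0.5) == pytest.approx(
                    binom_two_tailed(n - k, n, 0.5)
                )

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            binom_two_tailed(0, 0, 0.5)


class TestKsTwoSample:
    def test_identical_samples(self):
        d, _ = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_fully_separated(self):
        d, p = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0
        assert p < 0.2

    def test_statistic_matches_ecdf_sweep(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        y = rng.normal(0.5, size=35)
        d, _ = ks_two_sample(x, y)
        grid = np.sort(np.concatenate([x, y]))
        ecdf = lambda s, t: np.mean(np.asarray(s) <= t)
        d_oracle = max(abs(ecdf(x, t) - ecdf(y, t)) for t in grid)
        assert d == pytest.approx(d_oracle)


class TestFisher:
    def test_balanced_table(self):
        odds, p = fisher_2x2(10, 10, 10, 10)
        assert odds == 1.0
        assert p == 1.0

    def test_perfect_separation(self):
        _, p = fisher_2x2(5, 0, 0, 5)
        assert p == pytest.approx(2 / math.comb(10, 5), rel=1e-9)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, p = fisher_2x2(a, b, c, d)
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-6)


class TestFractionsAndRate:
    def test_printed_percentages_from_counts(self):
        table = class_fractions({"DEL": 1377, "other": 1870 - 1377}).set_index("sv_class")
        assert table.loc["DEL", "pct"] == 73.6

    def test_rate(self):
        assert dnsv_rate(1870, 13698) == pytest.approx(1870 / 13698)
        assert dnsv_rate(0, 10) == 0.0
        with pytest.raises(ValueError):
            dnsv_rate(1, 0)


class TestTelomereBinning:
    def test_event_counts_conserved(self):
        g = grch38().autosomes()
        rng = np.random.default_rng(21)
        chroms = sorted(g.chrom_lengths)
        events = [
            (c, int(rng.integers(0, g.chrom_lengths[c])))
            for c in rng.choice(chroms, size=500)
        ]
        binned = telomere_binning(events, g)
        assert binned.total_events == 500

    def test_all_events_at_chromosome_start_fall_in_first_bin(self):
        g = grch38().autosomes()
        events = [(c, 0) for c in g.chrom_lengths]
        binned = telomere_binning(events, g)
        assert binned.events_per_bin[0] == len(events)
        assert binned.events_per_bin[1:].sum() == 0

    def test_position_beyond_chromosome_rejected(self):
        g = grch38().autosomes()
        with pytest.raises(Exception):
            telomere_binning([("chr21", 10**9)], g)

    def test_printed_density_ratio(self):
        assert round(density_ratio(1.3, 0.457), 1) == 2.8

    def test_uniform_events_ratio_near_one(self):
        g = grch38().autosomes()
        rng = np.random.default_rng(22)
        lengths = g.chrom_lengths
        chroms = sorted(lengths)
        weights = np.array([lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        events = []
        for _ in range(10_000):
            c = chroms[int(rng.choice(len(chroms), p=weights))]
            events.append((c, int(rng.integers(0, lengths[c]))))
        ratio = subtelomeric_ratio(events, g)
        assert ratio == pytest.approx(1.0, abs=0.05)


class TestPermutationEnrichment:
    WORKSPACE = [("chr1", 0, 10_000_000)]

    def test_targets_equal_workspace(self):
        rng = np.random.default_rng(1)
        res = permutation_enrichment(
            [("chr1", 100_000, 150_000)], self.WORKSPACE, self.WORKSPACE,
            n_samples=200, rng=rng,
        )
        assert res.ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_enrichment_hits_p_floor(self):
        rng = np.random.default_rng(2)
        targets = [("chr1", 0, 100_000)]  # 1% of workspace
        query = [("chr1", i * 10_000, i * 10_000 + 5_000) for i in range(8)]
        res = permutation_enrichment(query, targets, self.WORKSPACE,
                                     n_samples=1000, rng=rng)
        assert res.p_value == pytest.approx(1 / 1001)
        assert res.ratio > 10

    def test_zero_overlap_depletion(self):
        rng = np.random.default_rng(3)
        res = permutation_enrichment(
            [("chr1", 9_000_000, 9_050_000)], [("chr1", 0, 1_000_000)],
            self.WORKSPACE, n_samples=200, rng=rng,
        )
        assert res.observed == 0
        assert res.ratio < 1
        assert res.p_value > 0.5

    def test_expected_overlap_matches_analytic_mean(self):
        rng = np.random.default_rng(4)
        L, coverage = 50_000, 0.2
        targets = [("chr1", 0, int(10_000_000 * coverage))]
        res = permutation_enrichment(
            [("chr1", 5_000_000, 5_000_000 + L)], targets, self.WORKSPACE,
            n_samples=1000, rng=rng,
        )
        analytic = L * coverage
        # overlap of one placement lies in [0, L]: SE of the mean <= L/2/sqrt(n)
        bound = 3 * (L / 2) / math.sqrt(res.n_samples)
        assert abs(res.expected - analytic) <= bound

    def test_window_extension_applied(self):
        rng = np.random.default_rng(5)
        targets = [("chr1", 200_000, 210_000)]
        query = [("chr1", 150_000, 160_000)]  # touches target only with 50 kb window
        res0 = permutation_enrichment(query, targets, self.WORKSPACE, 50, 0, rng)
        res50 = permutation_enrichment(query, targets, self.WORKSPACE, 50, 50_000, rng)
        assert res0.observed == 0
        assert res50.observed > 0

    def test_oversized_interval_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            permutation_enrichment(
                [("chr1", 0, 2_000_000)], [("chr1", 0, 10)], [("chr1", 0, 1_000_000)],
                n_samples=10, rng=np.random.default_rng(0),
            )

    def test_seeded_reproducibility(self):
        targets = [("chr1", 0, 500_000)]
        query = [("chr1", 100_000, 130_000)]
        a = permutation_enrichment(query, targets, self.WORKSPACE, 300, 0,
                                   np.random.default_rng(77))
        b = permutation_enrichment(query, targets, self.WORKSPACE, 300, 0,
                                   np.random.default_rng(77))
        assert (a.expected, a.p_value) == (b.expected, b.p_value)


class TestDetectability:
    EXONS = [("chr1", 1000 * i, 1000 * i + 200) for i in range(1, 20)]

    def test_two_exon_deletion_not_detectable(self):
        assert detectability_class("DEL", [("chr1", 900, 2_300)], self.EXONS) == (
            "not_detectable"
        )

    def test_balanced_classes_not_detectable(self):
        assert detectability_class("RECIPROCAL_INV", [], self.EXONS) == "not_detectable"
        assert detectability_class("RECIPROCAL_TRA", [], self.EXONS) == "not_detectable"

    def test_many_exon_deletion_detectable(self):
        assert detectability_class("DEL", [("chr1", 500, 12_000)], self.EXONS) == (
            "array_wes_detectable"
        )

    def test_three_exon_boundary(self):
        span = [("chr1", 900, 3_300)]  # overlaps exons at 1000, 2000, 3000
        assert detectability_class("DEL", span, self.EXONS) == "array_wes_detectable"
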