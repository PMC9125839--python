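import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from tspfunc import (
    GenomicInterval,
    PermutationNull,
    Thresholds,
    binomial_category_enrichment,
    empirical_p,
    eqtl_tissue_enrichment,
    permutation_overlap_test,
    regulatory_enrichment,
    shuffle_regions,
)
from tspfunc.enrichment import RegionShuffler, count_overlap_pairs

from conftest import make_region


def binomial_upper_tail_oracle(k, n, p):
    """Exact rational upper-tail P(X >= k) by term-wise integer summation
    (the shorter tail is summed and complemented when cheaper)."""
    p = Fraction(p)
    num, den = p.numerator, p.denominator
    q = den - num

    def mass(indices):
        return sum(math.comb(n, i) * num**i * q ** (n - i) for i in indices)

    if k <= n - k:
        numerator = den**n - mass(range(0, k))
    else:
        numerator = mass(range(k, n + 1))
    return Fraction(numerator, den**n)


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration: sum the
    probabilities of all tables with the same margins whose probability does
    not exceed the observed table's."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def prob(x):
        return (
            Fraction(math.comb(col1, x) * math.comb(n - col1, row1 - x), math.comb(n, row1))
        )

    observed = prob(a)
    lo, hi = max(0, row1 - (n - col1)), min(row1, col1)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= observed:
            total += px
    return total


class TestShuffleRegions:
    chrom_sizes = {"chr1": 10_000, "chr2": 8_000}

    def test_forced_placement(self):
        """Exclusions leaving exactly one region-length run force the start."""
        sizes = {"chr1": 1000}
        exclusions = [GenomicInterval("chr1", 0, 400), GenomicInterval("chr1", 500, 1000)]
        region = GenomicInterval("chr1", 0, 100)
        # [400, 500) is the only gap and exactly fits the 100-bp region
        out = shuffle_regions([region], sizes, exclusions, seed=5)
        assert out == [GenomicInterval("chr1", 400, 500)]

    def test_no_valid_placement_names_chromosome(self):
        sizes = {"chr1": 1000}
        exclusions = [GenomicInterval("chr1", 0, 950)]
        with pytest.raises(ValueError, match="chr1"):
            shuffle_regions([GenomicInterval("chr1", 0, 100)], sizes, exclusions, seed=0)

    def test_invariant_sweep(self):
        """Every draw preserves per-chromosome length multisets and avoids
        the exclusion set entirely."""
        regions = [
            GenomicInterval("chr1", 100, 400),
            GenomicInterval("chr1", 1_000, 1_050),
            GenomicInterval("chr2", 0, 700),
            GenomicInterval("chr2", 900, 905),
            GenomicInterval("chr2", 2_000, 2_500),
        ]
        exclusions = [GenomicInterval("chr1", 4_000, 5_000), GenomicInterval("chr2", 0, 500)]
        rng = np.random.default_rng(11)
        shuffler = RegionShuffler(regions, self.chrom_sizes, exclusions)
        want = sorted((r.chrom, r.length) for r in regions)
        for _ in range(1000):
            draw = shuffler.one_draw(rng)
            assert sorted((r.chrom, r.length) for r in draw) == want
            for iv in draw:
                assert 0 <= iv.start and iv.end <= self.chrom_sizes[iv.chrom]
                for ex in exclusions:
                    assert not (
                        ex.chrom == iv.chrom and iv.start < ex.end and ex.start < iv.end
                    )

    def test_placement_uniform_over_valid_starts(self):
        """Chi-square goodness of fit of start positions against the
        enumerated valid-start set on a toy chromosome."""
        sizes = {"chr1": 120}
        exclusions = [GenomicInterval("chr1", 30, 40), GenomicInterval("chr1", 80, 90)]
        length = 10
        valid = [
            s
            for s in range(sizes["chr1"] - length + 1)
            if all(not (s < ex.end and ex.start < s + length) for ex in exclusions)
        ]
        shuffler = RegionShuffler([GenomicInterval("chr1", 0, length)], sizes, exclusions)
        rng = np.random.default_rng(2)
        starts = shuffler.sample_starts(rng, 10_000)[:, 0]
        assert set(np.unique(starts)) <= set(valid)
        observed = np.array([(starts == s).sum() for s in valid])
        chi2, p = stats.chisquare(observed)
        assert p > 0.01


class TestEmpiricalP:
    def test_observed_above_all_nulls_gives_add_one_minimum(self):
        null = PermutationNull(1000, observed=50, null_values=np.zeros(1000, dtype=int), seed=0)
        assert empirical_p(null) == pytest.approx(1 / 1001)

    def test_observed_equal_to_every_null_gives_one(self):
        null = PermutationNull(100, observed=5, null_values=np.full(100, 5), seed=0)
        assert empirical_p(null) == pytest.approx(1.0)

    def test_hand_counted_example(self):
        null = PermutationNull(5, observed=3, null_values=np.array([0, 1, 2, 3, 4]), seed=0)
        assert empirical_p(null, "enrichment") == pytest.approx(0.5)  # (1 + 2) / 6
        assert empirical_p(null, "depletion") == pytest.approx(5 / 6)

    def test_never_zero_and_minimum_halves_with_doubled_permutations(self):
        for n_perm in (100, 200):
            null = PermutationNull(n_perm, 10**9, np.zeros(n_perm, dtype=int), seed=0)
            assert empirical_p(null) == pytest.approx(1 / (n_perm + 1))

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            PermutationNull(0, 0, np.array([]), seed=0)


class TestBinomialEnrichment:
    def test_zero_hits_give_p_one(self):
        (res,) = binomial_category_enrichment({}, 10, {"cat": 0.1})
        assert res.p_value == pytest.approx(1.0)

    def test_exact_tail_example(self):
        (res,) = binomial_category_enrichment({"cat": 5}, 10, {"cat": 0.1})
        oracle = float(binomial_upper_tail_oracle(5, 10, Fraction(1, 10)))
        assert res.p_value == pytest.approx(oracle, rel=1e-12)
        assert res.p_value == pytest.approx(1.63e-3, rel=5e-3)

    @pytest.mark.parametrize(
        "k, n, p0",
        [(0, 50, 0.2), (3, 17, 0.05), (50, 100, 0.5), (990, 1000, 0.97),
         (120, 10_000, 0.01), (9_990, 10_000, 0.999)],
    )
    def test_tail_matches_exact_summation_oracle(self, k, n, p0):
        (res,) = binomial_category_enrichment({"c": k}, n, {"c": p0})
        oracle = binomial_upper_tail_oracle(k, n, Fraction(str(p0)))
        assert res.p_value == pytest.approx(float(oracle), rel=1e-12)

    def test_bonferroni_cutoff_over_394_categories(self):
        probs = {"target": 0.01}
        just_below = binomial_category_enrichment({"target": 6}, 20, probs, n_categories=394)[0]
        # cutoff is 0.05/394 = 1.269e-4; p(X>=6 | 20, 0.01) ~ 5e-9 clears it
        assert just_below.adjusted_tier == "bonferroni_significant"
        nominal = binomial_category_enrichment({"target": 2}, 20, probs, n_categories=394)[0]
        assert 0.05 / 394 < nominal.p_value < 0.05
        assert nominal.adjusted_tier == "nominal"

    def test_hits_above_total_rejected(self):
        with pytest.raises(ValueError):
            binomial_category_enrichment({"c": 11}, 10, {"c": 0.1})


class TestTissueEnrichment:
    def test_no_association(self):
        (res,) = eqtl_tissue_enrichment({"t": 5}, 10, {"t": 5}, 10)
        assert res.effect == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_odds_ratio(self):
        (res,) = eqtl_tissue_enrichment({"t": 10}, 100, {"t": 5}, 900)
        assert res.effect == pytest.approx((10 * 895) / (90 * 5), rel=1e-12)  # 19.89

    def test_zero_cell_gets_haldane_anscombe_correction(self):
        (res,) = eqtl_tissue_enrichment({"t": 0}, 10, {"t": 5}, 100)
        assert res.corrected is True
        assert math.isfinite(res.effect) and res.effect > 0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            eqtl_tissue_enrichment({"t": 11}, 10, {"t": 0}, 10)

    @pytest.mark.parametrize(
        "a, b, c, d",
        [(2, 8, 5, 5), (0, 10, 10, 0), (7, 3, 2, 8), (1, 1, 1, 1), (12, 38, 25, 125),
         (40, 60, 30, 70)],
    )
    def test_fisher_p_matches_hypergeometric_enumeration(self, a, b, c, d):
        (res,) = eqtl_tissue_enrichment({"t": a}, a + b, {"t": c}, c + d)
        oracle = float(fisher_two_sided_oracle(a, b, c, d))
        assert res.p_value == pytest.approx(oracle, rel=1e-9)


class TestPermutationOverlapTest:
    def test_observed_matches_brute_force_count(self, rng):
        chrom_sizes = {"chr1": 50_000}
        queries = [GenomicInterval("chr1", int(s), int(s) + 500) for s in rng.integers(0, 49_000, 20)]
        features = [GenomicInterval("chr1", int(s), int(s) + 100) for s in rng.integers(0, 49_000, 50)]
        brute = sum(1 for q in queries for f in features if q.start < f.end and f.start < q.end)
        assert count_overlap_pairs(queries, features) == brute
        null = permutation_overlap_test(queries, features, chrom_sizes, n_perm=50, seed=1)
        assert null.observed == brute

    def test_reproducible_under_fixed_seed(self):
        chrom_sizes = {"chr1": 100_000}
        queries = [GenomicInterval("chr1", 10, 1000), GenomicInterval("chr1", 5_000, 5_600)]
        features = [GenomicInterval("chr1", 50_000, 50_200)]
        a = permutation_overlap_test(queries, features, chrom_sizes, n_perm=100, seed=42)
        b = permutation_overlap_test(queries, features, chrom_sizes, n_perm=100, seed=42)
        assert np.array_equal(a.null_values, b.null_values)

    def test_shuffling_features_role_supported(self):
        chrom_sizes = {"chr1": 100_000}
        queries = [GenomicInterval("chr1", 10, 1000)]
        features = [GenomicInterval("chr1", 500, 600), GenomicInterval("chr1", 90_000, 90_100)]
        null = permutation_overlap_test(
            queries, features, chrom_sizes, n_perm=200, seed=0, shuffle="features"
        )
        assert null.observed == 1
        assert null.null_values.max() <= 2


class TestRegulatoryEnrichment:
    def test_tiers_and_null_summaries(self):
        rng = np.random.default_rng(8)
        chrom_sizes = {"chr1": 200_000}
        regions = [
            make_region(f"r{i}", "chr1", (int(p) + 1, int(p) + 2000), beta_max=2.5)
            for i, p in enumerate(rng.integers(0, 190_000, 12))
        ]
        enriched_class = [
            GenomicInterval("chr1", r.interval.start, r.interval.start + 100) for r in regions
        ]
        sparse_class = [GenomicInterval("chr1", 195_000, 195_100)]
        results = regulatory_enrichment(
            regions,
            {"enhancer": enriched_class, "promoter": sparse_class},
            chrom_sizes,
            thresholds=Thresholds(n_permutations=500),
            seed=3,
        )
        by_label = {r.label: r for r in results}
        assert by_label["enhancer"].p_value < 0.05
        assert by_label["enhancer"].adjusted_tier in {"bonferroni_significant", "nominal"}
        assert by_label["promoter"].p_value > by_label["enhancer"].p_value
        for r in results:
            assert r.null_summary is not None
            assert r.null_summary["min"] <= r.null_summary["mean"] <= r.null_summary["max"]
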