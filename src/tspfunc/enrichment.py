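"""Enrichment statistics: constrained region permutation, binomial category
tests, and per-tissue odds ratios.

The permutation null shuffles query regions across the genome preserving
each region's length and chromosome, avoiding a merged exclusion set
(assembly gaps + blacklist + MHC), with placement exactly uniform over the
valid start positions of each chromosome.  The observed statistic is the
number of (query interval, feature) overlapping pairs, and the empirical
p-value uses the add-one estimator p = (1 + #{null as-or-more-extreme}) /
(1 + n_perm), which can never return 0 and counts ties conservatively.

Category enrichment is the one-sided upper-tail exact binomial
P(X >= k | n, p0) with Bonferroni correction over the number of categories
tested; tissue enrichment is an odds ratio per 2x2 table with the
Haldane–Anscombe +0.5 correction when any cell is empty and a two-sided
Fisher exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval, SPRegion, Thresholds, merge_intervals

TIER_BONFERRONI = "bonferroni_significant"
TIER_NOMINAL = "nominal"
TIER_NS = "not_significant"


@dataclass
class PermutationNull:
    """The observed statistic and its permutation null distribution."""

    n_perm: int
    observed: int
    null_values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values)
        if self.n_perm <= 0:
            raise ValueError("n_perm must be positive")
        if self.null_values.shape != (self.n_perm,):
            raise ValueError("null_values length must equal n_perm")
        if (self.null_values < 0).any() or self.observed < 0:
            raise ValueError("overlap statistics must be non-negative")


@dataclass
class EnrichmentResult:
    """One labelled enrichment outcome with its significance tier."""

    label: str
    statistic_kind: str  # empirical_p | binomial_p | odds_ratio
    observed: float
    expected: float
    effect: float
    p_value: float
    adjusted_tier: str
    corrected: bool = False
    null_summary: Optional[dict] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"{self.label}: p-value must lie in (0, 1], got {self.p_value}")
        if self.adjusted_tier not in {TIER_BONFERRONI, TIER_NOMINAL, TIER_NS}:
            raise ValueError(f"unknown tier {self.adjusted_tier!r}")


def _tier(p: float, alpha: float, n_tests: int) -> str:
    if p < alpha / n_tests:
        return TIER_BONFERRONI
    if p < alpha:
        return TIER_NOMINAL
    return TIER_NS


# ---------------------------------------------------------------------------
# Constrained shuffling
# ---------------------------------------------------------------------------

@dataclass
class _PlacementSpace:
    """Valid start positions for a region of a given length on one chromosome,
    as runs [lo, hi] of consecutive valid starts."""

    run_lo: np.ndarray
    run_counts: np.ndarray
    total: int


def _valid_runs(chrom_size: int, exclusions: Sequence[GenomicInterval], length: int) -> _PlacementSpace:
    """Enumerate maximal runs of valid 0-based starts for a ``length``-bp
    region: starts s with [s, s+L) inside [0, chrom_size) and disjoint from
    every exclusion."""
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for ex in exclusions:  # assumed merged + sorted
        if ex.start > cursor:
            gaps.append((cursor, ex.start))
        cursor = max(cursor, ex.end)
    if cursor < chrom_size:
        gaps.append((cursor, chrom_size))
    lows, counts = [], []
    for g0, g1 in gaps:
        hi = g1 - length
        if hi >= g0:
            lows.append(g0)
            counts.append(hi - g0 + 1)
    lows_arr = np.array(lows, dtype=np.int64)
    counts_arr = np.array(counts, dtype=np.int64)
    return _PlacementSpace(lows_arr, counts_arr, int(counts_arr.sum()))


class RegionShuffler:
    """Uniform constrained placement of a fixed set of intervals.

    Each input interval keeps its chromosome and length; its shuffled start
    is drawn uniformly over all starts whose placement avoids the exclusion
    set.  Placements of distinct regions are independent (shuffled regions
    may overlap one another, matching bedtools-shuffle defaults)."""

    def __init__(
        self,
        intervals: Sequence[GenomicInterval],
        chrom_sizes: Mapping[str, int],
        exclusions: Sequence[GenomicInterval] = (),
    ) -> None:
        self.intervals = list(intervals)
        merged = merge_intervals(list(exclusions))
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for ex in merged:
            by_chrom.setdefault(ex.chrom, []).append(ex)
        self._spaces: list[_PlacementSpace] = []
        for iv in self.intervals:
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"no chromosome size for {iv.chrom}")
            space = _valid_runs(chrom_sizes[iv.chrom], by_chrom.get(iv.chrom, []), iv.length)
            if space.total == 0:
                raise ValueError(
                    f"no valid placement for a {iv.length}-bp region on {iv.chrom}"
                )
            self._spaces.append(space)

    def sample_starts(self, rng: np.random.Generator, n_draws: int = 1) -> np.ndarray:
        """(n_draws, n_regions) matrix of shuffled start positions."""
        out = np.empty((n_draws, len(self.intervals)), dtype=np.int64)
        for j, space in enumerate(self._spaces):
            flat = rng.integers(0, space.total, size=n_draws)
            run = np.searchsorted(np.cumsum(space.run_counts), flat, side="right")
            offset = flat - np.concatenate(([0], np.cumsum(space.run_counts)))[run]
            out[:, j] = space.run_lo[run] + offset
        return out

    def one_draw(self, rng: np.random.Generator) -> list[GenomicInterval]:
        starts = self.sample_starts(rng, 1)[0]
        return [
            GenomicInterval(iv.chrom, int(s), int(s) + iv.length)
            for iv, s in zip(self.intervals, starts)
        ]


def shuffle_regions(
    regions: Sequence[SPRegion | GenomicInterval],
    chrom_sizes: Mapping[str, int],
    exclusions: Sequence[GenomicInterval] = (),
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """One constrained shuffle of the query regions (see RegionShuffler)."""
    intervals = [r.interval if isinstance(r, SPRegion) else r for r in regions]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return RegionShuffler(intervals, chrom_sizes, exclusions).one_draw(rng)


# ---------------------------------------------------------------------------
# Overlap counting and the permutation test
# ---------------------------------------------------------------------------

def count_overlap_pairs(
    queries: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> int:
    """Number of (query, feature) pairs sharing at least one bp."""
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {f.chrom for f in features}:
        on = [f for f in features if f.chrom == chrom]
        starts[chrom] = np.sort(np.array([f.start for f in on], dtype=np.int64))
        ends[chrom] = np.sort(np.array([f.end for f in on], dtype=np.int64))
    total = 0
    for q in queries:
        if q.chrom not in starts:
            continue
        n_before_end = np.searchsorted(starts[q.chrom], q.end, side="left")
        n_closed = np.searchsorted(ends[q.chrom], q.start, side="right")
        total += int(n_before_end - n_closed)
    return int(total)


def permutation_overlap_test(
    queries: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    exclusions: Sequence[GenomicInterval] = (),
    n_perm: int = 1000,
    seed: int = 0,
    shuffle: str = "queries",
) -> PermutationNull:
    """Permutation null of the pair-overlap count between queries and
    features.  ``shuffle`` selects which side is randomized across the
    genome ("queries", the default, or "features")."""
    if shuffle not in {"queries", "features"}:
        raise ValueError("shuffle must be 'queries' or 'features'")
    observed = count_overlap_pairs(queries, features)
    moving, fixed = (queries, features) if shuffle == "queries" else (features, queries)
    shuffler = RegionShuffler(list(moving), chrom_sizes, exclusions)
    rng = np.random.default_rng(seed)

    fixed_starts: dict[str, np.ndarray] = {}
    fixed_ends: dict[str, np.ndarray] = {}
    for chrom in {f.chrom for f in fixed}:
        on = [f for f in fixed if f.chrom == chrom]
        fixed_starts[chrom] = np.sort(np.array([f.start for f in on], dtype=np.int64))
        fixed_ends[chrom] = np.sort(np.array([f.end for f in on], dtype=np.int64))

    starts_matrix = shuffler.sample_starts(rng, n_perm)  # (n_perm, n_moving)
    lengths = np.array([iv.length for iv in shuffler.intervals], dtype=np.int64)
    null = np.zeros(n_perm, dtype=np.int64)
    for j, iv in enumerate(shuffler.intervals):
        if iv.chrom not in fixed_starts:
            continue
        s = starts_matrix[:, j]
        e = s + lengths[j]
        a = np.searchsorted(fixed_starts[iv.chrom], e, side="left")
        b = np.searchsorted(fixed_ends[iv.chrom], s, side="right")
        null += a - b
    return PermutationNull(n_perm=n_perm, observed=observed, null_values=null, seed=seed)


def empirical_p(null: PermutationNull, direction: str = "enrichment") -> float:
    """Add-one empirical p-value, counting ties as as-or-more-extreme."""
    if direction == "enrichment":
        extreme = int((null.null_values >= null.observed).sum())
    elif direction == "depletion":
        extreme = int((null.null_values <= null.observed).sum())
    else:
        raise ValueError("direction must be 'enrichment' or 'depletion'")
    return (1 + extreme) / (1 + null.n_perm)


def regulatory_enrichment(
    regions: Sequence[SPRegion],
    features_by_class: Mapping[str, Sequence[GenomicInterval]],
    chrom_sizes: Mapping[str, int],
    exclusions: Sequence[GenomicInterval] = (),
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
    shuffle: str = "queries",
) -> list[EnrichmentResult]:
    """Per-feature-class permutation enrichment of the query regions, with
    the Bonferroni denominator set to the number of classes tested."""
    intervals = [r.interval for r in regions]
    n_tests = max(len(features_by_class), 1)
    seeds = np.random.SeedSequence(seed).spawn(len(features_by_class))
    results = []
    for (label, feats), sub_seed in zip(sorted(features_by_class.items()), seeds):
        class_seed = int(sub_seed.generate_state(1)[0] % (2**31))
        null = permutation_overlap_test(
            intervals,
            list(feats),
            chrom_sizes,
            exclusions,
            n_perm=thresholds.n_permutations,
            seed=class_seed,
            shuffle=shuffle,
        )
        p = empirical_p(null, "enrichment")
        expected = float(null.null_values.mean())
        effect = null.observed / expected if expected > 0 else float("inf")
        results.append(
            EnrichmentResult(
                label=label,
                statistic_kind="empirical_p",
                observed=float(null.observed),
                expected=expected,
                effect=effect,
                p_value=p,
                adjusted_tier=_tier(p, thresholds.alpha, n_tests),
                null_summary={
                    "mean": expected,
                    "sd": float(null.null_values.std(ddof=1)) if null.n_perm > 1 else 0.0,
                    "min": float(null.null_values.min()),
                    "max": float(null.null_values.max()),
                },
            )
        )
    return results


# ---------------------------------------------------------------------------
# Binomial category enrichment
# ---------------------------------------------------------------------------

def binomial_category_enrichment(
    hits_per_category: Mapping[str, int],
    total_hits: int,
    background_prob_per_category: Mapping[str, float],
    n_categories: Optional[int] = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided upper-tail exact binomial test per trait category.

    For category c with k observed hits out of n total and background
    probability p0 across the full catalog, p = P(X >= k | n, p0); the
    Bonferroni tier uses alpha / n_categories (the number of categories
    tested, defaulting to the number of background categories supplied).
    """
    if total_hits < 0:
        raise ValueError("total_hits must be non-negative")
    if n_categories is None:
        n_categories = len(background_prob_per_category)
    if n_categories <= 0:
        raise ValueError("n_categories must be positive")
    results = []
    for label in sorted(background_prob_per_category):
        p0 = background_prob_per_category[label]
        if not 0.0 < p0 < 1.0:
            raise ValueError(f"background probability for {label!r} must lie in (0, 1)")
        k = int(hits_per_category.get(label, 0))
        if k < 0 or k > total_hits:
            raise ValueError(f"category {label!r}: hits {k} outside [0, {total_hits}]")
        p = float(stats.binom.sf(k - 1, total_hits, p0))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        expected = total_hits * p0
        results.append(
            EnrichmentResult(
                label=label,
                statistic_kind="binomial_p",
                observed=float(k),
                expected=expected,
                effect=k / expected if expected > 0 else float("inf"),
                p_value=p,
                adjusted_tier=_tier(p, alpha, n_categories),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Per-tissue odds ratios
# ---------------------------------------------------------------------------

def eqtl_tissue_enrichment(
    fg_counts_per_tissue: Mapping[str, int],
    fg_total: int,
    bg_counts_per_tissue: Mapping[str, int],
    bg_total: int,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-tissue odds ratio of foreground vs background eQTL membership.

    Each tissue contributes the 2x2 table [[a, b], [c, d]] with a = fg hits,
    b = fg misses, c = bg hits, d = bg misses.  The odds ratio gets the
    Haldane–Anscombe +0.5 correction on all cells when any cell is zero
    (flagged ``corrected``); the p-value is the two-sided Fisher exact test
    on the uncorrected table.  Bonferroni is over the tissues tested.
    """
    tissues = sorted(set(fg_counts_per_tissue) | set(bg_counts_per_tissue))
    n_tests = max(len(tissues), 1)
    results = []
    for tissue in tissues:
        a = int(fg_counts_per_tissue.get(tissue, 0))
        c = int(bg_counts_per_tissue.get(tissue, 0))
        b = fg_total - a
        d = bg_total - c
        if min(a, b, c, d) < 0:
            raise ValueError(f"tissue {tissue!r}: negative 2x2 cell (a={a} b={b} c={c} d={d})")
        corrected = 0 in (a, b, c, d)
        if corrected:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            aa, bb, cc, dd = a, b, c, d
        odds_ratio = (aa * dd) / (bb * cc)
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        expected = (a + c) * fg_total / (fg_total + bg_total) if fg_total + bg_total else 0.0
        results.append(
            EnrichmentResult(
                label=tissue,
                statistic_kind="odds_ratio",
                observed=float(a),
                expected=expected,
                effect=float(odds_ratio),
                p_value=p,
                adjusted_tier=_tier(p, alpha, n_tests),
                corrected=corrected,
            )
        )
    return results


def write_enrichment(path, results: Sequence[EnrichmentResult]) -> None:
    columns = (
        "label",
        "statistic_kind",
        "observed",
        "expected",
        "effect",
        "p_value",
        "adjusted_tier",
        "corrected",
        "null_mean",
        "null_sd",
        "null_min",
        "null_max",
    )
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(columns) + "\n")
        for r in sorted(results, key=lambda x: (x.statistic_kind, x.label)):
            ns = r.null_summary or {}
            out.write(
                "\t".join(
                    [
                        r.label,
                        r.statistic_kind,
                        f"{r.observed:g}",
                        f"{r.expected:g}",
                        f"{r.effect:g}",
                        f"{r.p_value:.6g}",
                        r.adjusted_tier,
                        str(int(r.corrected)),
                        *(f"{ns[k]:g}" if k in ns else "" for k in ("mean", "sd", "min", "max")),
                    ]
                )
                + "\n"
            )
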