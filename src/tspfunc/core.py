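"""Domain types and interval algebra shared by every pipeline stage.

Coordinates are BED-style 0-based half-open internally.  Variant tables and
VCF input are 1-based and converted at the I/O boundary: a variant at 1-based
position ``pos`` occupies the half-open interval ``[pos - 1, pos)``.  Strand
is ignored throughout (all inputs are strand-agnostic point variants and
regulatory intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Variant",
    "SPRegion",
    "Thresholds",
    "overlaps",
    "intersect_variants",
    "merge_intervals",
    "normalize_chrom",
    "chrom_style",
]


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chrN`` convention.

    Bare ``1``..``22``, ``X``, ``Y`` and ``MT``/``M`` gain a ``chr`` prefix;
    anything else (unplaced contigs, scaffolds) passes through untouched.
    """
    name = name.strip()
    if not name:
        raise ValueError("empty chromosome name")
    if name.startswith("chr"):
        return name
    body = name.upper()
    if body == "MT":
        body = "M"
    if body in {"X", "Y", "M"} or body.isdigit():
        return f"chr{body}"
    return name


def chrom_style(name: str) -> str:
    """Classify a chromosome name as ``chr``-prefixed or ``bare``."""
    return "chr" if name.startswith("chr") else "bare"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos: int) -> bool:
        """True iff the 1-based position ``pos`` falls inside this interval."""
        return self.start < pos <= self.end


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test: true iff the intervals share at least one bp."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class Variant:
    """A point variant identified by rsID at a 1-based position."""

    rsid: str
    chrom: str
    pos: int
    ref: Optional[str] = None
    alt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.rsid}: 1-based position must be >= 1, got {self.pos}")

    @property
    def interval(self) -> GenomicInterval:
        """The equivalent 0-based half-open interval ``[pos - 1, pos)``."""
        return GenomicInterval(self.chrom, self.pos - 1, self.pos)

    def has_rsid(self) -> bool:
        return bool(self.rsid) and self.rsid != "."


@dataclass
class SPRegion:
    """A candidate haplotype region carrying clustered human–chimp shared polymorphisms.

    Holds the per-region evidence consumed by the tier cascade: the maximum
    standardized BetaScan2 score over member variants (``beta_max``), the set
    of populations with an NCD balancing-selection call, and the ARGweaver
    TMRCA estimate in generations.  Absent evidence is ``None`` / empty and is
    treated as "no evidence", never as an error.
    """

    region_id: str
    interval: GenomicInterval
    sp_variants: list[Variant]
    tmrca_generations: Optional[float] = None
    beta_max: Optional[float] = None
    ncd_populations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.ncd_populations = frozenset(self.ncd_populations)
        if len(self.sp_variants) < 2:
            raise ValueError(
                f"region {self.region_id}: needs >= 2 shared polymorphisms, got {len(self.sp_variants)}"
            )
        rsids = [v.rsid for v in self.sp_variants]
        if len(set(rsids)) != len(rsids):
            raise ValueError(f"region {self.region_id}: duplicate SP rsids")
        for v in self.sp_variants:
            if v.chrom != self.interval.chrom or not self.interval.contains_pos(v.pos):
                raise ValueError(
                    f"region {self.region_id}: SP {v.rsid} at {v.chrom}:{v.pos} "
                    f"lies outside {self.interval.chrom}:{self.interval.start}-{self.interval.end}"
                )
        if self.tmrca_generations is not None and self.tmrca_generations < 0:
            raise ValueError(f"region {self.region_id}: negative TMRCA {self.tmrca_generations}")

    @property
    def sp_count(self) -> int:
        return len(self.sp_variants)

    @property
    def sp_rsids(self) -> list[str]:
        return [v.rsid for v in self.sp_variants]


@dataclass(frozen=True)
class Thresholds:
    """All tunable cutoffs of the triage and annotation cascade.

    Defaults follow the study conventions: proxy LD at r² ≥ 0.8, the
    standardized BetaScan2 cutoff of 2.0, the ARGweaver age cutoff of 140,000
    generations, ≥ 3 clustered SPs for the trans-species tier, genome-wide
    significance at 5e-8 (GWAS, inclusive) and 1e-8 (PheWAS, strict), the
    eQTL reporting threshold of 5e-5, and 1000 permutations with Bonferroni
    over 394 trait categories.
    """

    r2_min: float = 0.8
    beta_min: float = 2.0
    tmrca_min_generations: float = 140_000.0
    ctsp_min_sp: int = 3
    gwas_p_max: float = 5e-8
    phewas_p_max: float = 1e-8
    eqtl_p_max: float = 5e-5
    n_permutations: int = 1000
    alpha: float = 0.05
    efo_category_count: int = 394

    def __post_init__(self) -> None:
        for name in (
            "r2_min",
            "beta_min",
            "tmrca_min_generations",
            "ctsp_min_sp",
            "n_permutations",
            "efo_category_count",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        for name in ("gwas_p_max", "phewas_p_max", "eqtl_p_max", "alpha"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"threshold {name} must lie in (0, 1), got {value}")


def _check_shared_style(chroms: Iterable[str]) -> None:
    seen: dict[str, str] = {}
    for chrom in chroms:
        seen.setdefault(chrom_style(chrom), chrom)
    if len(seen) > 1:
        examples = " vs ".join(sorted(seen.values()))
        raise ValueError(
            f"mixed chromosome naming conventions: {examples}; normalize inputs before intersecting"
        )


def intersect_variants(
    variants: Sequence[Variant], features: Sequence[GenomicInterval]
) -> list[tuple[Variant, GenomicInterval]]:
    """All (variant, feature) pairs whose half-open projections overlap.

    Output order is deterministic: sorted by chromosome, variant position,
    then feature start/end.  Mixed chromosome naming conventions between the
    two sets are rejected rather than silently producing an empty join.
    """
    _check_shared_style(
        [v.chrom for v in variants] + [f.chrom for f in features]
    )
    trees: dict[str, IntervalTree] = {}
    # data carries the feature's list index so duplicated intervals survive
    for idx, feat in enumerate(features):
        trees.setdefault(feat.chrom, IntervalTree()).addi(feat.start, feat.end, idx)
    pairs: list[tuple[Variant, GenomicInterval]] = []
    for variant in variants:
        tree = trees.get(variant.chrom)
        if tree is None:
            continue
        for hit in tree.at(variant.pos - 1):
            pairs.append((variant, features[hit.data]))
    pairs.sort(key=lambda p: (p[0].chrom, p[0].pos, p[0].rsid, p[1].start, p[1].end))
    return pairs


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint set (bookended runs are merged)."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged
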