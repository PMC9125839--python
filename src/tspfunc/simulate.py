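"""Synthetic-data generator: every pipeline input with known ground truth.

The generator emulates the study's input shapes at a desk scale: clustered
shared polymorphisms (>= 2 within 4 kb) on a multi-chromosome toy genome,
per-region balancing-selection evidence (standardized Beta scores, NCD
population calls) and TMRCA draws from a young/ancient mixture, phased
haplotype panels with block LD structure at a tunable r² target, a
regulatory feature track with a planted fold-enrichment inside the query
regions, and GWAS/PheWAS/eQTL catalogs with planted per-category and
per-tissue excess.  A truth table records each region's intended tier, each
tag's true proxy set (r² recomputed from the generated haplotypes), and the
planted folds, so every downstream stage can be checked end to end.

LD blocks copy a founder haplotype within each block and inject independent
flip noise at rate eps = (1 - t^(1/4)) / 2, which gives expected pairwise
r² ≈ t between block members without coalescent machinery.  Everything is
drawn from a single numpy Generator, so one seed fixes the whole bundle.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as io_formats
from .core import GenomicInterval, SPRegion, Thresholds, Variant, merge_intervals
from .io import (
    CatalogRecord,
    EqtlRecord,
    FEATURE_CLASSES,
    GTEX_TISSUES,
    RegulatoryFeature,
)
from .ld import HaplotypePanel, compute_r2

DEFAULT_CATEGORIES = (
    "immune system disorder",
    "hematological measurement",
    "body measurement",
    "cognitive performance",
    "lipid or lipoprotein measurement",
    "metabolic disorder",
    "lifestyle and environment",
    "neurological disorder",
)


def _default_chrom_sizes() -> dict[str, int]:
    return {f"chr{i}": 8_000_000 for i in range(1, 6)}


def _default_sp_probs() -> dict[int, float]:
    return {2: 0.80, 3: 0.15, 4: 0.05}


@dataclass
class SimConfig:
    """All knobs of the synthetic bundle; defaults are the study-scale
    conditions (125 regions, 60 expected cbSP, ~19 expected ctSP)."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_regions: int = 125
    sp_per_region_probs: dict[int, float] = field(default_factory=_default_sp_probs)
    cluster_span_bp: int = 4000
    min_region_separation_bp: int = 50_000
    # balancing-selection evidence (study: 60/125 Beta-supported, 18/125 NCD)
    fraction_with_high_beta: float = 0.48
    fraction_with_ncd: float = 0.144
    ncd_mode: str = "nested"  # NCD calls a subset of Beta regions, or "disjoint"
    beta_high_range: tuple[float, float] = (2.0, 4.0)
    beta_low_range: tuple[float, float] = (0.0, 1.99)
    fraction_beta_missing: float = 0.10
    # TMRCA mixture in generations
    tmrca_old_fraction: float = 0.15
    fraction_tmrca_missing: float = 0.20
    tmrca_old_range: tuple[float, float] = (140_000.0, 300_000.0)
    tmrca_young_range: tuple[float, float] = (10_000.0, 120_000.0)
    # haplotype panels
    populations: tuple[str, ...] = ("AFR", "EAS", "EUR")
    n_haplotypes: int = 100
    block_variants: int = 12
    decoy_variants: int = 6
    block_r2_target: float = 0.9
    fraction_no_rsid: float = 0.05
    ld_window_bp: int = 500_000
    # regulatory feature track
    n_features: int = 5000
    feature_length_bp: int = 800
    feature_fold: float = 1.0
    n_exclusions_per_chrom: int = 2
    exclusion_length_bp: int = 150_000
    # association catalogs
    n_categories: int = 20
    n_planted_categories: int = 3
    gwas_background_rows: int = 4000
    phewas_background_rows: int = 3000
    fraction_regions_with_gwas: float = 0.25
    gwas_variants_per_region: tuple[int, int] = (1, 5)
    fraction_regions_with_phewas: float = 0.18
    phewas_variants_per_region: tuple[int, int] = (5, 25)
    signal_p_range: tuple[float, float] = (1e-12, 1e-8)
    background_p_range: tuple[float, float] = (1e-12, 1e-4)
    # eQTL catalog (study: 64/133 SPs are eQTL)
    fraction_sp_eqtl: float = 0.48
    eqtl_tissues_per_hit: tuple[int, int] = (1, 5)
    eqtl_background_rows: int = 4000
    eqtl_signal_p_range: tuple[float, float] = (1e-10, 4.9e-5)
    eqtl_background_p_range: tuple[float, float] = (1e-8, 1e-2)
    planted_eqtl_tissues: tuple[str, ...] = (
        "Liver",
        "Whole Blood",
        "Pancreas",
        "Skin - Sun Exposed (Lower leg)",
    )
    eqtl_planted_tissue_weight: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "fraction_with_high_beta",
            "fraction_with_ncd",
            "fraction_beta_missing",
            "tmrca_old_fraction",
            "fraction_tmrca_missing",
            "fraction_no_rsid",
            "fraction_regions_with_gwas",
            "fraction_regions_with_phewas",
            "fraction_sp_eqtl",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.feature_fold < 1.0:
            raise ValueError("feature_fold must be >= 1")
        if not math.isclose(sum(self.sp_per_region_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("sp_per_region_probs must sum to 1")
        if min(self.sp_per_region_probs) < 2:
            raise ValueError("regions need at least 2 SPs")
        if not 0.0 < self.block_r2_target <= 1.0:
            raise ValueError("block_r2_target must lie in (0, 1]")
        if self.ncd_mode not in {"nested", "disjoint"}:
            raise ValueError("ncd_mode must be 'nested' or 'disjoint'")


@dataclass
class SimBundle:
    """Everything simulate_dataset produced, as in-memory objects."""

    config: SimConfig
    regions: list[SPRegion]
    panels: list[HaplotypePanel]
    features: list[RegulatoryFeature]
    exclusions: list[GenomicInterval]
    chrom_sizes: dict[str, int]
    eqtl_catalog: list[EqtlRecord]
    gwas_catalog: list[CatalogRecord]
    phewas_catalogs: dict[str, list[CatalogRecord]]
    truth: pd.DataFrame
    truth_proxies: dict[str, set[str]]

    def write(self, outdir: str | Path, thresholds: Optional[Thresholds] = None) -> dict[str, Path]:
        """Write the bundle in the formats the pipeline readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "regions_bed": outdir / "regions.bed",
            "regions_meta": outdir / "regions_meta.tsv",
            "features": outdir / "features.bed",
            "exclusions": outdir / "exclusions.bed",
            "chrom_sizes": outdir / "chrom.sizes",
            "eqtl": outdir / "eqtl.tsv",
            "gwas": outdir / "gwas.tsv",
            "truth": outdir / "truth.tsv",
            "truth_proxies": outdir / "truth_proxies.tsv",
        }
        io_formats.write_regions(paths["regions_bed"], paths["regions_meta"], self.regions, thresholds)
        io_formats.write_feature_track(paths["features"], self.features)
        io_formats.write_bed(paths["exclusions"], self.exclusions)
        io_formats.write_chrom_sizes(paths["chrom_sizes"], self.chrom_sizes)
        io_formats.write_eqtl(paths["eqtl"], self.eqtl_catalog)
        io_formats.write_catalog(paths["gwas"], self.gwas_catalog)
        for source, catalog in sorted(self.phewas_catalogs.items()):
            paths[source] = outdir / f"{source}.tsv"
            io_formats.write_catalog(paths[source], catalog)
        for panel in self.panels:
            key = f"panel_{panel.population}"
            paths[key] = outdir / f"panel_{panel.population}.vcf"
            io_formats.write_panel_vcf(paths[key], panel, self.chrom_sizes)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["truth_proxies"], "w", encoding="utf-8") as out:
            out.write("tag_rsid\tproxy_rsids\n")
            for tag in sorted(self.truth_proxies):
                out.write(f"{tag}\t{','.join(sorted(self.truth_proxies[tag]))}\n")
        return paths


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return 10 ** rng.uniform(math.log10(lo), math.log10(hi), size=size)


def _placeable_runs(
    chrom_sizes: Mapping[str, int], exclusions: Sequence[GenomicInterval]
) -> list[tuple[str, int, int]]:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for ex in merge_intervals(list(exclusions)):
        by_chrom.setdefault(ex.chrom, []).append(ex)
    runs = []
    for chrom in sorted(chrom_sizes):
        cursor = 0
        for ex in by_chrom.get(chrom, []):
            if ex.start > cursor:
                runs.append((chrom, cursor, ex.start))
            cursor = max(cursor, ex.end)
        if cursor < chrom_sizes[chrom]:
            runs.append((chrom, cursor, chrom_sizes[chrom]))
    return runs


def _sample_bp(rng: np.random.Generator, runs: Sequence[tuple[str, int, int]]) -> tuple[str, int]:
    lengths = np.array([r[2] - r[1] for r in runs], dtype=np.int64)
    flat = int(rng.integers(0, lengths.sum()))
    idx = int(np.searchsorted(np.cumsum(lengths), flat, side="right"))
    offset = flat - int(np.concatenate(([0], np.cumsum(lengths)))[idx])
    chrom, lo, _ = runs[idx]
    return chrom, lo + offset


def plant_feature_enrichment(
    region_intervals: Sequence[GenomicInterval],
    fold: float,
    n_features: int,
    feature_length_bp: int,
    chrom_sizes: Mapping[str, int],
    exclusions: Sequence[GenomicInterval] = (),
    seed: int | np.random.Generator = 0,
    classes: Sequence[str] = tuple(sorted(FEATURE_CLASSES)),
) -> list[RegulatoryFeature]:
    """Place features so that the expected per-bp density inside the query
    regions is ``fold`` times the outside density.

    A feature midpoint lands inside the region union with probability
    fold·R / (fold·R + G_out) where R is the union's bp and G_out the
    remaining non-excluded bp; within each side placement is uniform.
    """
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    placeable = _placeable_runs(chrom_sizes, exclusions)
    placeable_bp = sum(r[2] - r[1] for r in placeable)
    if n_features * feature_length_bp > 0.8 * placeable_bp:
        raise ValueError(
            f"feature density too high: {n_features} x {feature_length_bp} bp cannot be "
            f"placed disjointly in {placeable_bp} placeable bp"
        )
    region_union = merge_intervals(list(region_intervals))
    inside_runs = [(iv.chrom, iv.start, iv.end) for iv in region_union]
    region_bp = sum(iv.length for iv in region_union)
    # outside = placeable minus the region union
    exclusions_plus_regions = merge_intervals(list(exclusions) + list(region_union))
    outside_runs = _placeable_runs(chrom_sizes, exclusions_plus_regions)
    outside_bp = sum(r[2] - r[1] for r in outside_runs)
    p_in = fold * region_bp / (fold * region_bp + outside_bp) if region_bp else 0.0

    features = []
    class_list = list(classes)
    for _ in range(n_features):
        if region_bp and rng.random() < p_in:
            chrom, mid = _sample_bp(rng, inside_runs)
        else:
            chrom, mid = _sample_bp(rng, outside_runs)
        start = max(0, min(mid - feature_length_bp // 2, chrom_sizes[chrom] - feature_length_bp))
        feature_class = class_list[int(rng.integers(0, len(class_list)))]
        features.append(
            RegulatoryFeature(GenomicInterval(chrom, start, start + feature_length_bp), feature_class)
        )
    features.sort(key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end, f.feature_class))
    return features


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig = SimConfig()) -> SimBundle:
    """Generate the full input bundle with ground truth (see module docstring)."""
    rng = np.random.default_rng(config.seed)

    # exclusions first (regions and features avoid them)
    exclusions: list[GenomicInterval] = []
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        for _ in range(config.n_exclusions_per_chrom):
            start = int(rng.integers(0, max(1, size - config.exclusion_length_bp)))
            exclusions.append(GenomicInterval(chrom, start, start + config.exclusion_length_bp))
    exclusions = merge_intervals(exclusions)

    placeable = _placeable_runs(config.chrom_sizes, exclusions)
    placeable_bp = sum(r[2] - r[1] for r in placeable)
    footprint = config.cluster_span_bp + config.min_region_separation_bp
    if config.n_regions * footprint > placeable_bp:
        raise ValueError(
            f"infeasible config: {config.n_regions} regions x {footprint} bp footprint "
            f"exceed {placeable_bp} placeable bp"
        )

    # region anchors: uniform in placeable space, min separation enforced
    anchors: list[tuple[str, int]] = []
    placed: dict[str, list[int]] = {}
    for _ in range(config.n_regions):
        for _attempt in range(1000):
            chrom, bp = _sample_bp(rng, placeable)
            if bp + config.cluster_span_bp > config.chrom_sizes[chrom]:
                continue
            span = GenomicInterval(chrom, bp, bp + config.cluster_span_bp)
            if any(ex.chrom == chrom and ex.start < span.end and bp < ex.end for ex in exclusions):
                continue
            if all(
                abs(bp - other) >= config.cluster_span_bp + config.min_region_separation_bp
                for other in placed.get(chrom, [])
            ):
                anchors.append((chrom, bp))
                placed.setdefault(chrom, []).append(bp)
                break
        else:
            raise ValueError("could not place all regions; loosen separation or enlarge genome")
    anchors.sort()

    sp_counts = rng.choice(
        list(config.sp_per_region_probs),
        size=config.n_regions,
        p=list(config.sp_per_region_probs.values()),
    )

    # evidence planting
    n_beta = round(config.fraction_with_high_beta * config.n_regions)
    n_ncd = round(config.fraction_with_ncd * config.n_regions)
    order = rng.permutation(config.n_regions)
    beta_set = set(order[:n_beta].tolist())
    if config.ncd_mode == "nested":
        ncd_pool = order[:n_beta] if n_beta >= n_ncd else order
        ncd_set = set(rng.choice(ncd_pool, size=min(n_ncd, len(ncd_pool)), replace=False).tolist())
    else:
        rest = order[n_beta : n_beta + n_ncd]
        ncd_set = set(rest.tolist())

    rsid_counter = 0

    def next_rsid() -> str:
        nonlocal rsid_counter
        rsid_counter += 1
        return f"rs{rsid_counter:06d}"

    regions: list[SPRegion] = []
    truth_rows = []
    block_positions: dict[str, list[tuple[str, int, bool]]] = {}  # region -> (rsid, pos, is_sp)
    for i, (chrom, anchor) in enumerate(anchors):
        k = int(sp_counts[i])
        n_extra = max(config.block_variants - k, 0)
        positions = rng.choice(np.arange(1, config.cluster_span_bp), size=k + n_extra, replace=False)
        positions = np.sort(positions) + anchor  # 1-based within (anchor, anchor+span)
        sp_idx = set(rng.choice(k + n_extra, size=k, replace=False).tolist())
        members = []
        sp_variants = []
        for j, pos in enumerate(positions):
            is_sp = j in sp_idx
            if is_sp or rng.random() > config.fraction_no_rsid:
                rsid = next_rsid()
            else:
                rsid = "."
            members.append((rsid, int(pos), is_sp))
            if is_sp:
                sp_variants.append(Variant(rsid, chrom, int(pos)))
        region_id = f"region_{i:03d}"
        block_positions[region_id] = members
        interval = GenomicInterval(chrom, sp_variants[0].pos - 1, sp_variants[-1].pos)

        has_beta = i in beta_set
        has_ncd = i in ncd_set
        if has_beta:
            beta = float(rng.uniform(*config.beta_high_range))
        elif rng.random() < config.fraction_beta_missing:
            beta = None
        else:
            beta = float(rng.uniform(*config.beta_low_range))
        ncd_pops = frozenset()
        if has_ncd:
            n_pops = int(rng.integers(1, len(config.populations) + 1))
            ncd_pops = frozenset(
                rng.choice(config.populations, size=n_pops, replace=False).tolist()
            )
        if rng.random() < config.fraction_tmrca_missing:
            tmrca = None
        elif rng.random() < config.tmrca_old_fraction:
            tmrca = float(rng.uniform(*config.tmrca_old_range))
        else:
            tmrca = float(rng.uniform(*config.tmrca_young_range))

        regions.append(
            SPRegion(
                region_id=region_id,
                interval=interval,
                sp_variants=sp_variants,
                tmrca_generations=tmrca,
                beta_max=beta,
                ncd_populations=ncd_pops,
            )
        )
        is_cbsp = has_beta or has_ncd
        is_ctsp = is_cbsp and (k >= 3 or (tmrca is not None and tmrca >= 140_000.0))
        truth_rows.append(
            {
                "region_id": region_id,
                "chrom": chrom,
                "start": interval.start,
                "end": interval.end,
                "sp_count": k,
                "beta_max": np.nan if beta is None else beta,
                "has_ncd": has_ncd,
                "tmrca_generations": np.nan if tmrca is None else tmrca,
                "true_tier": "ctsp" if is_ctsp else ("cbsp" if is_cbsp else "sp_only"),
            }
        )
    truth = pd.DataFrame(truth_rows)

    # haplotype panels with block LD structure
    eps = (1.0 - config.block_r2_target ** 0.25) / 2.0
    panels = []
    for population in config.populations:
        variants: list[Variant] = []
        columns: list[np.ndarray] = []
        for region in regions:
            members = block_positions[region.region_id]
            founder = (rng.random(config.n_haplotypes) < 0.5).astype(np.int8)
            if founder.min() == founder.max():
                founder[0] ^= 1
            for rsid, pos, _is_sp in members:
                flips = rng.random(config.n_haplotypes) < eps
                col = founder ^ flips.astype(np.int8)
                if col.min() == col.max():
                    col = col.copy()
                    col[int(rng.integers(0, config.n_haplotypes))] ^= 1
                variants.append(Variant(rsid, region.interval.chrom, pos))
                columns.append(col)
            # decoys: independent intermediate-frequency variants nearby
            chrom_size = config.chrom_sizes[region.interval.chrom]
            for _ in range(config.decoy_variants):
                offset = int(rng.integers(5000, 50_000)) * (1 if rng.random() < 0.5 else -1)
                pos = min(max(region.interval.start + offset, 1), chrom_size - 1)
                freq = rng.uniform(0.1, 0.9)
                col = (rng.random(config.n_haplotypes) < freq).astype(np.int8)
                if col.min() == col.max():
                    col[0] ^= 1
                variants.append(Variant(next_rsid(), region.interval.chrom, pos))
                columns.append(col)
        panels.append(
            HaplotypePanel(
                population=population,
                variants=variants,
                haplotypes=np.array(columns, dtype=np.int8).T,
            )
        )

    # truth proxy sets: brute-force r² over every panel, windowed by position
    truth_proxies: dict[str, set[str]] = {}
    for region in regions:
        for sp in region.sp_variants:
            truth_proxies[sp.rsid] = set()
    for panel in panels:
        by_chrom: dict[str, list[int]] = {}
        for j, v in enumerate(panel.variants):
            by_chrom.setdefault(v.chrom, []).append(j)
        rsid_to_col = {v.rsid: j for j, v in enumerate(panel.variants) if v.has_rsid()}
        for tag_rsid, proxies in truth_proxies.items():
            j = rsid_to_col.get(tag_rsid)
            if j is None:
                continue
            tag_variant = panel.variants[j]
            tag_col = panel.haplotypes[:, j]
            if tag_col.min() == tag_col.max():
                continue
            for k in by_chrom[tag_variant.chrom]:
                other = panel.variants[k]
                if k == j or not other.has_rsid() or other.rsid == tag_rsid:
                    continue
                if abs(other.pos - tag_variant.pos) > config.ld_window_bp:
                    continue
                col = panel.haplotypes[:, k]
                if col.min() == col.max():
                    continue
                if compute_r2(tag_col, col) >= 0.8:
                    proxies.add(other.rsid)

    # regulatory feature track with planted fold
    features = plant_feature_enrichment(
        [r.interval for r in regions],
        config.feature_fold,
        config.n_features,
        config.feature_length_bp,
        config.chrom_sizes,
        exclusions,
        seed=rng,
    )

    # cbSP-truth region universe drives catalog planting
    cbsp_regions = [r for r, row in zip(regions, truth_rows) if row["true_tier"] != "sp_only"]
    universe_by_region = {
        r.region_id: sorted(
            {v.rsid for v in r.sp_variants}
            | {p for v in r.sp_variants for p in truth_proxies[v.rsid]}
        )
        for r in cbsp_regions
    }

    categories = list(DEFAULT_CATEGORIES[: config.n_categories])
    for extra in range(len(categories), config.n_categories):
        categories.append(f"category_{extra:02d}")
    weights = 1.0 / np.arange(1, config.n_categories + 1)
    background_probs = weights / weights.sum()
    planted_categories = categories[: config.n_planted_categories]

    def background_catalog(n_rows: int, source: str, start_id: int) -> list[CatalogRecord]:
        cats = rng.choice(categories, size=n_rows, p=background_probs)
        pvals = _log_uniform(rng, *config.background_p_range, size=n_rows)
        return [
            CatalogRecord(
                rsid=f"rs9{start_id + i:06d}",
                chrom=None,
                pos=None,
                trait=f"{cats[i]} trait {i}",
                category=str(cats[i]),
                p_value=float(pvals[i]),
                source=source,
            )
            for i in range(n_rows)
        ]

    def planted_catalog(source: str, fraction: float, per_region: tuple[int, int]) -> list[CatalogRecord]:
        rows = []
        region_ids = sorted(universe_by_region)
        n_pick = round(fraction * len(region_ids))
        picked = rng.choice(region_ids, size=min(n_pick, len(region_ids)), replace=False)
        for region_id in sorted(picked):
            pool = universe_by_region[region_id]
            n_var = int(rng.integers(per_region[0], per_region[1] + 1))
            chosen = rng.choice(pool, size=min(n_var, len(pool)), replace=False)
            for rsid in sorted(chosen):
                category = planted_categories[int(rng.integers(0, len(planted_categories)))]
                rows.append(
                    CatalogRecord(
                        rsid=str(rsid),
                        chrom=None,
                        pos=None,
                        trait=f"{category} planted trait",
                        category=category,
                        p_value=float(_log_uniform(rng, *config.signal_p_range)),
                        source=source,
                    )
                )
        return rows

    gwas_catalog = background_catalog(config.gwas_background_rows, "gwas_catalog", 0)
    gwas_catalog += planted_catalog(
        "gwas_catalog", config.fraction_regions_with_gwas, config.gwas_variants_per_region
    )
    phewas_catalogs = {}
    for offset, source in enumerate(("phewas_geneatlas", "phewas_nealelab")):
        catalog = background_catalog(
            config.phewas_background_rows, source, 100_000 * (offset + 1)
        )
        catalog += planted_catalog(
            source, config.fraction_regions_with_phewas / 2, config.phewas_variants_per_region
        )
        phewas_catalogs[source] = catalog

    # eQTL catalog: planted SP hits with tissue excess, plus background rows
    tissue_weights = np.ones(len(GTEX_TISSUES))
    for i, tissue in enumerate(GTEX_TISSUES):
        if tissue in config.planted_eqtl_tissues:
            tissue_weights[i] = config.eqtl_planted_tissue_weight
    tissue_probs = tissue_weights / tissue_weights.sum()
    eqtl_catalog: list[EqtlRecord] = []
    gene_counter = 0
    for region in cbsp_regions:
        for sp in region.sp_variants:
            if rng.random() >= config.fraction_sp_eqtl:
                continue
            gene_counter += 1
            gene = f"ENSG{gene_counter:08d}"
            lo, hi = config.eqtl_tissues_per_hit
            n_tissues = int(rng.integers(lo, hi + 1))
            tissues = rng.choice(GTEX_TISSUES, size=n_tissues, replace=False, p=tissue_probs)
            for tissue in tissues:
                eqtl_catalog.append(
                    EqtlRecord(
                        rsid=sp.rsid,
                        gene_id=gene,
                        tissue=str(tissue),
                        p_value=float(_log_uniform(rng, *config.eqtl_signal_p_range)),
                    )
                )
    bg_tissues = rng.choice(GTEX_TISSUES, size=config.eqtl_background_rows)
    bg_pvals = _log_uniform(rng, *config.eqtl_background_p_range, size=config.eqtl_background_rows)
    for i in range(config.eqtl_background_rows):
        eqtl_catalog.append(
            EqtlRecord(
                rsid=f"rs8{i:06d}",
                gene_id=f"ENSGBG{i:06d}",
                tissue=str(bg_tissues[i]),
                p_value=float(bg_pvals[i]),
            )
        )

    return SimBundle(
        config=config,
        regions=regions,
        panels=panels,
        features=features,
        exclusions=exclusions,
        chrom_sizes=dict(config.chrom_sizes),
        eqtl_catalog=eqtl_catalog,
        gwas_catalog=gwas_catalog,
        phewas_catalogs=phewas_catalogs,
        truth=truth,
        truth_proxies=truth_proxies,
    )
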