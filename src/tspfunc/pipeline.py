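"""End-to-end orchestration: filter -> ld-expand -> annotate -> enrich -> summarize.

A PipelineConfig names every input file, the thresholds, a single seed and
an output directory.  The global seed is expanded into per-stage substreams
with ``numpy.random.SeedSequence(seed).spawn``, so each stage can be rerun
independently with identical randomness.  The run manifest records per-stage
row counts, the thresholds actually applied, and a sha256 checksum of every
output file; reruns with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as io_formats
from .annotate import annotate_all, build_universe, write_annotations
from .core import Thresholds
from .enrichment import (
    binomial_category_enrichment,
    eqtl_tissue_enrichment,
    regulatory_enrichment,
    write_enrichment,
)
from .evidence import build_matrix, summarize, write_summary
from .filters import classify_regions, tier_counts, write_tiers
from .ld import expand_ld, write_proxies

STAGES = ("filter", "ld_expand", "annotate", "enrich", "summarize")


@dataclass
class PipelineConfig:
    regions_bed: str
    regions_meta: str
    out_dir: str
    panels: dict[str, str] = field(default_factory=dict)  # population -> path
    features: Optional[str] = None
    features_dialect: str = "bed"
    eqtl: Optional[str] = None
    gwas: Optional[str] = None
    phewas: dict[str, str] = field(default_factory=dict)  # source -> path
    exclusions: Optional[str] = None
    chrom_sizes: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    ld_window_bp: int = 500_000
    stages: tuple[str, ...] = STAGES
    shuffle: str = "queries"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle)
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        stages = tuple(raw.pop("stages", STAGES))
        return cls(thresholds=thresholds, stages=stages, **raw)

    def validate(self) -> None:
        for label, path in self.input_paths().items():
            if not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path} does not exist")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    def input_paths(self) -> dict[str, str]:
        paths = {"regions_bed": self.regions_bed, "regions_meta": self.regions_meta}
        for pop, path in self.panels.items():
            paths[f"panel_{pop}"] = path
        for source, path in self.phewas.items():
            paths[source] = path
        for name in ("features", "eqtl", "gwas", "exclusions", "chrom_sizes"):
            value = getattr(self, name)
            if value is not None:
                paths[name] = value
        return paths


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds
    stage_seeds = {
        stage: int(seq.generate_state(1)[0] % (2**31))
        for stage, seq in zip(STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES)))
    }
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "thresholds": dataclasses.asdict(thresholds),
        "stages": {},
        "outputs": {},
    }

    regions = io_formats.read_regions(config.regions_bed, config.regions_meta)
    manifest["stages"]["input"] = {"n_regions": len(regions)}

    # --- filter -----------------------------------------------------------
    assignments = classify_regions(regions, thresholds)
    tiers_path = out_dir / "tiers.tsv"
    if "filter" in config.stages:
        write_tiers(tiers_path, assignments)
        manifest["stages"]["filter"] = tier_counts(assignments)
    by_id = {r.region_id: r for r in regions}
    cbsp_regions = [by_id[a.region_id] for a in assignments if a.tier in {"cbsp", "ctsp"}]

    # --- ld expand --------------------------------------------------------
    panels = [
        io_formats.read_panel(path, population)
        for population, path in sorted(config.panels.items())
    ]
    proxy_sets = []
    if "ld_expand" in config.stages and panels:
        tags = [v for r in cbsp_regions for v in r.sp_variants]
        proxy_sets = expand_ld(tags, panels, thresholds, config.ld_window_bp)
        write_proxies(out_dir / "proxies.tsv", proxy_sets)
        manifest["stages"]["ld_expand"] = {
            "n_tags": len(tags),
            "n_proxies": len({p.rsid for ps in proxy_sets for p in ps.proxies}),
            "n_total_variants": len(
                {p.rsid for ps in proxy_sets for p in ps.proxies} | {ps.tag_rsid for ps in proxy_sets}
            ),
        }

    # --- annotate ---------------------------------------------------------
    universe = build_universe(cbsp_regions, proxy_sets, panels)
    annotations = []
    eqtl_catalog = io_formats.read_eqtl(config.eqtl) if config.eqtl else []
    catalogs = []
    if config.gwas:
        catalogs.append(io_formats.read_catalog(config.gwas, "gwas_catalog"))
    for source, path in sorted(config.phewas.items()):
        catalogs.append(io_formats.read_catalog(path, source))
    features = (
        io_formats.read_feature_track(config.features, config.features_dialect)
        if config.features
        else []
    )
    if "annotate" in config.stages:
        annotations = annotate_all(universe, features, eqtl_catalog, catalogs, thresholds)
        write_annotations(out_dir / "annotations.tsv", annotations)
        manifest["stages"]["annotate"] = {
            "n_universe": len(universe),
            "n_records": len(annotations),
        }

    # --- enrich -----------------------------------------------------------
    if "enrich" in config.stages:
        results = []
        if features and config.chrom_sizes:
            chrom_sizes = io_formats.read_chrom_sizes(config.chrom_sizes)
            exclusions = (
                io_formats.read_exclusions(config.exclusions) if config.exclusions else []
            )
            features_by_class: dict[str, list] = {}
            for f in features:
                features_by_class.setdefault(f.feature_class, []).append(f.interval)
            results += regulatory_enrichment(
                cbsp_regions,
                features_by_class,
                chrom_sizes,
                exclusions,
                thresholds,
                seed=stage_seeds["enrich"],
                shuffle=config.shuffle,
            )
        if config.gwas:
            gwas_catalog = catalogs[0]
            hit_rsids = {u.rsid for u in universe}
            hits: dict[str, int] = {}
            total_hits = 0
            for rec in gwas_catalog:
                if rec.rsid in hit_rsids and rec.p_value <= thresholds.gwas_p_max:
                    hits[rec.category] = hits.get(rec.category, 0) + 1
                    total_hits += 1
            background: dict[str, int] = {}
            for rec in gwas_catalog:
                background[rec.category] = background.get(rec.category, 0) + 1
            n_catalog = sum(background.values())
            probs = {c: n / n_catalog for c, n in background.items()}
            results += binomial_category_enrichment(
                hits, total_hits, probs, n_categories=len(probs), alpha=thresholds.alpha
            )
        if eqtl_catalog:
            sp_rsids = {v.rsid for r in cbsp_regions for v in r.sp_variants}
            fg = [r for r in eqtl_catalog if r.rsid in sp_rsids]
            bg = [r for r in eqtl_catalog if r.rsid not in sp_rsids]
            fg_counts: dict[str, int] = {}
            for rec in fg:
                fg_counts[rec.tissue] = fg_counts.get(rec.tissue, 0) + 1
            bg_counts: dict[str, int] = {}
            for rec in bg:
                bg_counts[rec.tissue] = bg_counts.get(rec.tissue, 0) + 1
            results += eqtl_tissue_enrichment(
                fg_counts, len(fg), bg_counts, len(bg), alpha=thresholds.alpha
            )
        write_enrichment(out_dir / "enrichment.tsv", results)
        manifest["stages"]["enrich"] = {"n_results": len(results)}

    # --- summarize --------------------------------------------------------
    if "summarize" in config.stages:
        matrix = build_matrix(annotations, cbsp_regions)
        io_formats.write_evidence_table(out_dir / "evidence_matrix.tsv", matrix, thresholds)
        summary = summarize(matrix)
        write_summary(out_dir / "summary.tsv", summary)
        manifest["stages"]["summarize"] = summary

    for path in sorted(out_dir.glob("*.tsv")):
        manifest["outputs"][path.name] = _sha256(path)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest
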