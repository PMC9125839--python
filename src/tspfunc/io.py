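"""Readers and writers for every external format the pipeline touches.

All readers validate strictly and fail with line numbers rather than
coercing malformed rows; all writers emit a deterministic column order and
sort, with a commented header stating the package version.  Gzip input is
supported transparently for text formats (suffix ``.gz``).

Variant tables, VCF and catalog positions are 1-based on disk and converted
to the internal 0-based half-open convention at this boundary.
"""

from __future__ import annotations

import csv
import gzip
import io as _stdio
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO

from . import __version__
from .core import GenomicInterval, SPRegion, Variant, merge_intervals, normalize_chrom

logger = logging.getLogger(__name__)

FEATURE_CLASSES = frozenset(
    {
        "open_chromatin",
        "promoter",
        "enhancer",
        "promoter_flanking",
        "ctcf_binding_site",
        "tf_binding_site",
    }
)

# Ensembl regulatory build SO-style feature types mapped onto the six classes.
GFF3_CLASS_MAP = {
    "open_chromatin_region": "open_chromatin",
    "promoter": "promoter",
    "enhancer": "enhancer",
    "promoter_flanking_region": "promoter_flanking",
    "CTCF_binding_site": "ctcf_binding_site",
    "TF_binding_site": "tf_binding_site",
}

CATALOG_SOURCES = frozenset({"gwas_catalog", "phewas_geneatlas", "phewas_nealelab"})

#: GTEx-style tissue vocabulary (50 labels) used to validate eQTL input.
GTEX_TISSUES = (
    "Adipose - Subcutaneous",
    "Adipose - Visceral (Omentum)",
    "Adrenal Gland",
    "Artery - Aorta",
    "Artery - Coronary",
    "Artery - Tibial",
    "Bladder",
    "Brain - Amygdala",
    "Brain - Anterior cingulate cortex (BA24)",
    "Brain - Caudate (basal ganglia)",
    "Brain - Cerebellar Hemisphere",
    "Brain - Cerebellum",
    "Brain - Cortex",
    "Brain - Frontal Cortex (BA9)",
    "Brain - Hippocampus",
    "Brain - Hypothalamus",
    "Brain - Nucleus accumbens (basal ganglia)",
    "Brain - Putamen (basal ganglia)",
    "Brain - Spinal cord (cervical c-1)",
    "Brain - Substantia nigra",
    "Breast - Mammary Tissue",
    "Cells - Cultured fibroblasts",
    "Cells - EBV-transformed lymphocytes",
    "Colon - Sigmoid",
    "Colon - Transverse",
    "Esophagus - Gastroesophageal Junction",
    "Esophagus - Mucosa",
    "Esophagus - Muscularis",
    "Heart - Atrial Appendage",
    "Heart - Left Ventricle",
    "Kidney - Cortex",
    "Liver",
    "Lung",
    "Minor Salivary Gland",
    "Muscle - Skeletal",
    "Nerve - Tibial",
    "Ovary",
    "Pancreas",
    "Pituitary",
    "Prostate",
    "Skin - Not Sun Exposed (Suprapubic)",
    "Skin - Sun Exposed (Lower leg)",
    "Small Intestine - Terminal Ileum",
    "Spleen",
    "Stomach",
    "Testis",
    "Thyroid",
    "Uterus",
    "Vagina",
    "Whole Blood",
)

#: Default hg19 MHC exclusion interval (configurable at every call site).
MHC_HG19 = GenomicInterval("chr6", 28_477_797, 33_448_354)


@dataclass(frozen=True)
class RegulatoryFeature:
    """One Ensembl-regulatory-build-style feature interval."""

    interval: GenomicInterval
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown regulatory feature class {self.feature_class!r}")


@dataclass(frozen=True)
class CatalogRecord:
    """One variant–trait association row from a GWAS/PheWAS catalog."""

    rsid: str
    chrom: Optional[str]
    pos: Optional[int]
    trait: str
    category: str
    p_value: float
    source: str

    def __post_init__(self) -> None:
        if self.source not in CATALOG_SOURCES:
            raise ValueError(f"unknown catalog source {self.source!r}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"catalog p-value must lie in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class EqtlRecord:
    """One variant–gene–tissue eQTL row."""

    rsid: str
    gene_id: str
    tissue: str
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"eQTL p-value must lie in (0, 1], got {self.p_value}")


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return _stdio.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _header_lines(thresholds=None) -> list[str]:
    lines = [f"# tspfunc {__version__}"]
    if thresholds is not None:
        parts = " ".join(f"{k}={v}" for k, v in vars(thresholds).items())
        lines.append(f"# thresholds: {parts}")
    return lines


def _iter_rows(handle: TextIO, delimiter: str = "\t"):
    """Yield (1-based line number, fields) skipping comment and blank lines."""
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split(delimiter)


def _parse_table(path: str | Path, required: Sequence[str]):
    """Parse a headered TSV; yield (lineno, dict).  Errors name missing columns."""
    with _open_text(path) as handle:
        rows = _iter_rows(handle)
        try:
            header_lineno, header = next(rows)
        except StopIteration:
            raise ValueError(f"{path}: empty table") from None
        missing = [col for col in required if col not in header]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
        index = {name: i for i, name in enumerate(header)}
        for lineno, fields in rows:
            if len(fields) < len(header):
                raise ValueError(f"{path} line {lineno}: expected {len(header)} fields")
            yield lineno, {name: fields[i] for name, i in index.items()}


# ---------------------------------------------------------------------------
# SP regions: BED + sidecar TSV
# ---------------------------------------------------------------------------

SIDECAR_COLUMNS = (
    "region_id",
    "sp_rsids",
    "sp_positions",
    "tmrca_generations",
    "beta_max",
    "ncd_populations",
)


def read_regions(bed_path: str | Path, sidecar_path: str | Path) -> list[SPRegion]:
    """Read SP regions from a BED file plus a sidecar TSV keyed by region_id.

    The sidecar carries the member SP rsids and 1-based positions, the
    region's TMRCA in generations, its maximum standardized Beta score, and
    the populations with an NCD call (all evidence fields may be empty).
    ``sp_count`` is recomputed from the rsid list, never trusted from file.
    """
    intervals: dict[str, GenomicInterval] = {}
    with _open_text(bed_path) as handle:
        for lineno, fields in _iter_rows(handle):
            if len(fields) < 4:
                raise ValueError(f"{bed_path} line {lineno}: need BED4 (chrom start end region_id)")
            chrom, start, end, region_id = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if region_id in intervals:
                raise ValueError(f"{bed_path} line {lineno}: duplicate region_id {region_id!r}")
            try:
                intervals[region_id] = GenomicInterval(normalize_chrom(chrom), start, end)
            except ValueError as exc:
                raise ValueError(f"{bed_path} line {lineno}: {exc}") from None

    regions: list[SPRegion] = []
    seen: set[str] = set()
    for lineno, row in _parse_table(sidecar_path, SIDECAR_COLUMNS):
        region_id = row["region_id"]
        if region_id in seen:
            raise ValueError(f"{sidecar_path} line {lineno}: duplicate region_id {region_id!r}")
        seen.add(region_id)
        if region_id not in intervals:
            raise ValueError(f"{sidecar_path} line {lineno}: region_id {region_id!r} not in BED")
        interval = intervals[region_id]
        rsids = [r for r in row["sp_rsids"].split(",") if r]
        positions = [int(p) for p in row["sp_positions"].split(",") if p]
        if len(rsids) != len(positions):
            raise ValueError(
                f"{sidecar_path} line {lineno}: {len(rsids)} rsids vs {len(positions)} positions"
            )
        variants = [Variant(r, interval.chrom, p) for r, p in zip(rsids, positions)]
        tmrca = float(row["tmrca_generations"]) if row["tmrca_generations"] else None
        beta = float(row["beta_max"]) if row["beta_max"] else None
        ncd = frozenset(p for p in row["ncd_populations"].split(",") if p)
        try:
            regions.append(
                SPRegion(
                    region_id=region_id,
                    interval=interval,
                    sp_variants=variants,
                    tmrca_generations=tmrca,
                    beta_max=beta,
                    ncd_populations=ncd,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{sidecar_path} line {lineno}: {exc}") from None

    orphans = set(intervals) - seen
    if orphans:
        raise ValueError(f"{sidecar_path}: no sidecar row for region(s) {sorted(orphans)}")
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.region_id))
    return regions


def write_regions(
    bed_path: str | Path, sidecar_path: str | Path, regions: Sequence[SPRegion], thresholds=None
) -> None:
    regions = sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start, r.region_id))
    with open(bed_path, "w", encoding="utf-8") as bed:
        for r in regions:
            bed.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.region_id}\n")
    with open(sidecar_path, "w", encoding="utf-8") as out:
        for line in _header_lines(thresholds):
            out.write(line + "\n")
        out.write("\t".join(SIDECAR_COLUMNS) + "\n")
        for r in regions:
            out.write(
                "\t".join(
                    [
                        r.region_id,
                        ",".join(v.rsid for v in r.sp_variants),
                        ",".join(str(v.pos) for v in r.sp_variants),
                        "" if r.tmrca_generations is None else f"{r.tmrca_generations:g}",
                        "" if r.beta_max is None else f"{r.beta_max:g}",
                        ",".join(sorted(r.ncd_populations)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Regulatory feature tracks
# ---------------------------------------------------------------------------

def read_feature_track(path: str | Path, dialect: str = "bed") -> list[RegulatoryFeature]:
    """Read a regulatory feature track in BED4 or GFF3 dialect.

    Feature types not mappable to the six-class vocabulary are dropped with a
    logged count; malformed coordinates fail with the line number.
    """
    if dialect not in {"bed", "gff3"}:
        raise ValueError(f"unknown feature-track dialect {dialect!r}")
    features: list[RegulatoryFeature] = []
    dropped = 0
    with _open_text(path) as handle:
        for lineno, fields in _iter_rows(handle):
            if dialect == "bed":
                if len(fields) < 4:
                    raise ValueError(f"{path} line {lineno}: need BED4 with a feature class")
                chrom, start, end, raw_class = fields[0], int(fields[1]), int(fields[2]), fields[3]
            else:
                if len(fields) < 5:
                    raise ValueError(f"{path} line {lineno}: truncated GFF3 row")
                chrom, raw_class = fields[0], fields[2]
                start, end = int(fields[3]) - 1, int(fields[4])  # GFF3 is 1-based inclusive
            feature_class = GFF3_CLASS_MAP.get(raw_class, raw_class)
            if feature_class not in FEATURE_CLASSES:
                dropped += 1
                continue
            if end <= start:
                raise ValueError(f"{path} line {lineno}: end <= start ({start}, {end})")
            features.append(
                RegulatoryFeature(GenomicInterval(normalize_chrom(chrom), start, end), feature_class)
            )
    if dropped:
        logger.info("read_feature_track(%s): dropped %d unknown-class features", path, dropped)
    features.sort(key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end, f.feature_class))
    return features


def write_feature_track(path: str | Path, features: Sequence[RegulatoryFeature]) -> None:
    rows = sorted(features, key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end))
    with open(path, "w", encoding="utf-8") as out:
        for f in rows:
            out.write(f"{f.interval.chrom}\t{f.interval.start}\t{f.interval.end}\t{f.feature_class}\n")


# ---------------------------------------------------------------------------
# Association and eQTL catalogs
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = ("rsid", "chrom", "pos", "trait", "category", "p_value")


def read_catalog(path: str | Path, source: str, dialect: str = "simple") -> list[CatalogRecord]:
    """Read a variant–trait association catalog.

    ``dialect="simple"`` expects columns rsid/chrom/pos/trait/category/p_value;
    ``dialect="gwas_catalog"`` accepts the standard GWAS-Catalog download
    columns (SNPS, CHR_ID, CHR_POS, MAPPED_TRAIT, P-VALUE), splitting
    multi-SNP rows on ";" and " x " delimiters.
    """
    if source not in CATALOG_SOURCES:
        raise ValueError(f"unknown catalog source {source!r}")
    records: list[CatalogRecord] = []
    if dialect == "simple":
        for lineno, row in _parse_table(path, CATALOG_COLUMNS):
            try:
                records.append(
                    CatalogRecord(
                        rsid=row["rsid"],
                        chrom=normalize_chrom(row["chrom"]) if row["chrom"] else None,
                        pos=int(row["pos"]) if row["pos"] else None,
                        trait=row["trait"],
                        category=row["category"],
                        p_value=float(row["p_value"]),
                        source=source,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from None
    elif dialect == "gwas_catalog":
        required = ("SNPS", "P-VALUE", "MAPPED_TRAIT")
        for lineno, row in _parse_table(path, required):
            snps = row["SNPS"].replace(" x ", ";").replace(",", ";")
            category = row.get("MAPPED_TRAIT_CATEGORY") or row["MAPPED_TRAIT"]
            for rsid in (s.strip() for s in snps.split(";")):
                if not rsid:
                    continue
                try:
                    records.append(
                        CatalogRecord(
                            rsid=rsid,
                            chrom=normalize_chrom(row["CHR_ID"]) if row.get("CHR_ID") else None,
                            pos=int(row["CHR_POS"]) if row.get("CHR_POS") else None,
                            trait=row["MAPPED_TRAIT"],
                            category=category,
                            p_value=float(row["P-VALUE"]),
                            source=source,
                        )
                    )
                except ValueError as exc:
                    raise ValueError(f"{path} line {lineno}: {exc}") from None
    else:
        raise ValueError(f"unknown catalog dialect {dialect!r}")
    records.sort(key=lambda r: (r.rsid, r.trait, r.p_value))
    return records


def write_catalog(path: str | Path, records: Sequence[CatalogRecord]) -> None:
    rows = sorted(records, key=lambda r: (r.rsid, r.trait, r.p_value))
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(CATALOG_COLUMNS) + "\n")
        for r in rows:
            out.write(
                f"{r.rsid}\t{r.chrom or ''}\t{'' if r.pos is None else r.pos}\t"
                f"{r.trait}\t{r.category}\t{r.p_value:.6g}\n"
            )


EQTL_COLUMNS = ("rsid", "gene_id", "tissue", "p_value")


def read_eqtl(
    path: str | Path, tissues: Optional[Iterable[str]] = GTEX_TISSUES
) -> list[EqtlRecord]:
    """Read an eQTL catalog; tissue labels are validated against ``tissues``
    (pass ``None`` to accept any non-empty label)."""
    vocab = None if tissues is None else frozenset(tissues)
    records: list[EqtlRecord] = []
    for lineno, row in _parse_table(path, EQTL_COLUMNS):
        tissue = row["tissue"]
        if not tissue:
            raise ValueError(f"{path} line {lineno}: empty tissue label")
        if vocab is not None and tissue not in vocab:
            raise ValueError(f"{path} line {lineno}: tissue {tissue!r} not in configured vocabulary")
        try:
            records.append(EqtlRecord(row["rsid"], row["gene_id"], tissue, float(row["p_value"])))
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from None
    records.sort(key=lambda r: (r.rsid, r.gene_id, r.tissue))
    return records


def write_eqtl(path: str | Path, records: Sequence[EqtlRecord]) -> None:
    rows = sorted(records, key=lambda r: (r.rsid, r.gene_id, r.tissue))
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(EQTL_COLUMNS) + "\n")
        for r in rows:
            out.write(f"{r.rsid}\t{r.gene_id}\t{r.tissue}\t{r.p_value:.6g}\n")


# ---------------------------------------------------------------------------
# Exclusions, chromosome sizes, generic BED
# ---------------------------------------------------------------------------

def read_exclusions(path: str | Path) -> list[GenomicInterval]:
    """Read an exclusion BED (gaps + blacklist + MHC); overlapping intervals
    are merged into a disjoint sorted set."""
    intervals: list[GenomicInterval] = []
    with _open_text(path) as handle:
        for lineno, fields in _iter_rows(handle):
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: need BED3")
            try:
                intervals.append(
                    GenomicInterval(normalize_chrom(fields[0]), int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from None
    return merge_intervals(intervals)


def write_bed(path: str | Path, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for iv in sorted(intervals):
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with _open_text(path) as handle:
        for lineno, fields in _iter_rows(handle):
            if len(fields) < 2:
                raise ValueError(f"{path} line {lineno}: need 'chrom\\tsize'")
            chrom = normalize_chrom(fields[0])
            size = int(fields[1])
            if size <= 0:
                raise ValueError(f"{path} line {lineno}: non-positive size for {chrom}")
            sizes[chrom] = size
    return sizes


def write_chrom_sizes(path: str | Path, sizes: dict[str, int]) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for chrom in sorted(sizes):
            out.write(f"{chrom}\t{sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# Haplotype panels: VCF (via pysam) or plain matrix TSV
# ---------------------------------------------------------------------------

def read_panel(path: str | Path, population: str):
    """Read a phased haplotype panel from a VCF or a haplotype-matrix TSV.

    VCF input must be fully phased; unphased genotypes are refused.
    Multi-allelic VCF sites are split into one 0/1 column per alternate
    allele (rsid suffixed ``_alt2``, ``_alt3``, ... beyond the first).
    """
    from .ld import HaplotypePanel  # local import to avoid a cycle

    path = Path(path)
    if path.suffix in {".vcf", ".gz"} and ".vcf" in path.name:
        return _read_panel_vcf(path, population)
    return _read_panel_matrix(path, population)


def _read_panel_vcf(path: Path, population: str):
    import numpy as np
    import pysam

    from .ld import HaplotypePanel

    variants: list[Variant] = []
    columns: list[list[int]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alleles_per_hap: list[int] = []
            for sample in samples:
                call = rec.samples[sample]
                if len(call["GT"]) > 1 and not call.phased:
                    raise ValueError(
                        f"{path}: unphased genotype for sample {sample} at "
                        f"{rec.chrom}:{rec.pos}; panel must be phased"
                    )
                if any(a is None for a in call["GT"]):
                    raise ValueError(f"{path}: missing allele at {rec.chrom}:{rec.pos}")
                alleles_per_hap.extend(call["GT"])
            rsid = rec.id or "."
            for alt_index in range(1, len(rec.alleles)):
                name = rsid if alt_index == 1 or rsid == "." else f"{rsid}_alt{alt_index}"
                variants.append(
                    Variant(
                        name,
                        normalize_chrom(rec.chrom),
                        rec.pos,
                        ref=rec.alleles[0],
                        alt=rec.alleles[alt_index],
                    )
                )
                columns.append([1 if a == alt_index else 0 for a in alleles_per_hap])
    if not variants:
        raise ValueError(f"{path}: empty panel")
    haplotypes = np.array(columns, dtype=np.int8).T
    return HaplotypePanel(population=population, variants=variants, haplotypes=haplotypes)


def _read_panel_matrix(path: Path, population: str):
    import numpy as np

    from .ld import HaplotypePanel

    variants: list[Variant] = []
    columns: list[list[int]] = []
    for lineno, row in _parse_table(path, ("rsid", "chrom", "pos", "haplotypes")):
        try:
            alleles = [int(c) for c in row["haplotypes"]]
        except ValueError:
            raise ValueError(f"{path} line {lineno}: haplotype string must be 0/1") from None
        variants.append(Variant(row["rsid"], normalize_chrom(row["chrom"]), int(row["pos"])))
        columns.append(alleles)
    haplotypes = np.array(columns, dtype=np.int8).T
    return HaplotypePanel(population=population, variants=variants, haplotypes=haplotypes)


def write_panel_matrix(path: str | Path, panel) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("rsid\tchrom\tpos\thaplotypes\n")
        for j, v in enumerate(panel.variants):
            hap = "".join(str(int(a)) for a in panel.haplotypes[:, j])
            out.write(f"{v.rsid}\t{v.chrom}\t{v.pos}\t{hap}\n")


def write_panel_vcf(path: str | Path, panel, chrom_sizes: Optional[dict[str, int]] = None) -> None:
    """Write a panel as a phased VCF (two haplotypes per synthetic diploid
    sample; an odd trailing haplotype becomes a haploid sample)."""
    n_hap = panel.haplotypes.shape[0]
    n_diploid = n_hap // 2
    with open(path, "w", encoding="utf-8") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##source=tspfunc-{__version__}\n")
        if chrom_sizes:
            for chrom in sorted(chrom_sizes):
                out.write(f"##contig=<ID={chrom},length={chrom_sizes[chrom]}>\n")
        else:
            for chrom in sorted({v.chrom for v in panel.variants}):
                length = max(v.pos for v in panel.variants if v.chrom == chrom) + 1000
                out.write(f"##contig=<ID={chrom},length={length}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        sample_names = [f"{panel.population}{i:04d}" for i in range(n_diploid)]
        if n_hap % 2:
            sample_names.append(f"{panel.population}h{n_diploid:04d}")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        out.write("\t".join(sample_names) + "\n")
        order = sorted(range(len(panel.variants)), key=lambda j: (panel.variants[j].chrom, panel.variants[j].pos))
        for j in order:
            v = panel.variants[j]
            col = panel.haplotypes[:, j]
            gts = ["|".join(str(int(a)) for a in col[2 * i : 2 * i + 2]) for i in range(n_diploid)]
            if n_hap % 2:
                gts.append(str(int(col[-1])))
            ref = v.ref or "A"
            alt = v.alt or "T"
            out.write(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t")
            out.write("\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Evidence tables
# ---------------------------------------------------------------------------

def write_evidence_table(path: str | Path, matrix, thresholds=None) -> None:
    """Serialize an EvidenceMatrix to TSV (LD-inclusive and SP-only views)."""
    frame = matrix.to_frame()
    with open(path, "w", encoding="utf-8") as out:
        for line in _header_lines(thresholds):
            out.write(line + "\n")
        frame.to_csv(out, sep="\t", index=False)


def read_evidence_table(path: str | Path):
    import pandas as pd

    with _open_text(path) as handle:
        lines = [ln for ln in handle if not ln.startswith("#")]
    return pd.read_csv(_stdio.StringIO("".join(lines)), sep="\t")
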