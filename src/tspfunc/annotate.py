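"""Attach lines of functional evidence to the cbSP-plus-proxy variant universe.

Four evidence classes are produced: ``regulatory`` (overlap with an
Ensembl-regulatory-build-style feature; no p-value), ``eqtl`` (catalog rows
at p ≤ eqtl_p_max), ``gwas`` (catalog rows at p ≤ gwas_p_max, inclusive) and
``phewas`` (biobank rows at p < phewas_p_max, strict).  Association matching
is by rsID, mirroring catalog joins; regulatory overlap needs coordinates
and therefore only annotates variants that carry them.  A region inherits an
annotation if any member SP or any of its LD proxies carries it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .core import Thresholds, Variant, intersect_variants
from .io import CatalogRecord, EqtlRecord, RegulatoryFeature

EVIDENCE_CLASSES = ("regulatory", "eqtl", "gwas", "phewas")

_SOURCE_TO_CLASS = {
    "gwas_catalog": "gwas",
    "phewas_geneatlas": "phewas",
    "phewas_nealelab": "phewas",
}


@dataclass(frozen=True)
class ExpandedVariant:
    """One member of the annotation universe: a tag SP or an LD proxy,
    attributed to its region."""

    rsid: str
    region_id: str
    is_tag_sp: bool
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def as_variant(self) -> Optional[Variant]:
        if self.chrom is None or self.pos is None:
            return None
        return Variant(self.rsid, self.chrom, self.pos)


@dataclass(frozen=True)
class AnnotationRecord:
    """One line of evidence attached to a variant, with provenance."""

    rsid: str
    region_id: str
    evidence_class: str
    detail: str
    is_tag_sp: bool
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise ValueError(f"unknown evidence class {self.evidence_class!r}")
        if self.evidence_class != "regulatory" and self.p_value is None:
            raise ValueError(f"{self.evidence_class} record requires a p-value")


def build_universe(
    regions, proxy_sets=None, panels: Sequence = ()
) -> list[ExpandedVariant]:
    """Assemble the annotation universe: every member SP of every region,
    plus (when proxy sets are given) each tag's LD proxies attributed to the
    tag's region.  Proxy coordinates are filled in from the panels when
    available so regulatory overlap can see them."""
    coord: dict[str, tuple[str, int]] = {}
    for panel in panels:
        for v in panel.variants:
            if v.has_rsid():
                coord.setdefault(v.rsid, (v.chrom, v.pos))

    universe: dict[tuple[str, str], ExpandedVariant] = {}
    tag_region: dict[str, str] = {}
    for region in regions:
        for v in region.sp_variants:
            tag_region[v.rsid] = region.region_id
            universe[(v.rsid, region.region_id)] = ExpandedVariant(
                v.rsid, region.region_id, True, v.chrom, v.pos
            )
    for ps in proxy_sets or ():
        region_id = tag_region.get(ps.tag_rsid)
        if region_id is None:
            raise ValueError(f"proxy set for unknown tag {ps.tag_rsid!r}")
        for proxy in ps.proxies:
            key = (proxy.rsid, region_id)
            if key in universe:
                continue  # an SP of the region is never demoted to proxy
            chrom_pos = coord.get(proxy.rsid, (None, None))
            universe[key] = ExpandedVariant(
                proxy.rsid, region_id, False, chrom_pos[0], chrom_pos[1]
            )
    return sorted(universe.values(), key=lambda v: (v.region_id, not v.is_tag_sp, v.rsid))


def annotate_regulatory(
    universe: Sequence[ExpandedVariant], features: Sequence[RegulatoryFeature]
) -> list[AnnotationRecord]:
    """One record per (variant, overlapping feature); nested or duplicated
    features each produce their own record."""
    located = [v for v in universe if v.as_variant() is not None]
    variants = [v.as_variant() for v in located]
    by_key = {}
    for ev in located:
        by_key.setdefault((ev.rsid, ev.chrom, ev.pos), []).append(ev)
    interval_class = {}
    for f in features:
        interval_class.setdefault(f.interval, []).append(f.feature_class)
    pairs = intersect_variants(list({v for v in variants}), list(interval_class))
    records = []
    for variant, interval in pairs:
        for feature_class in interval_class[interval]:
            for ev in by_key[(variant.rsid, variant.chrom, variant.pos)]:
                records.append(
                    AnnotationRecord(
                        ev.rsid, ev.region_id, "regulatory", feature_class, ev.is_tag_sp
                    )
                )
    records.sort(key=lambda r: (r.region_id, r.rsid, r.detail))
    return records


def annotate_eqtl(
    universe: Sequence[ExpandedVariant],
    eqtl_catalog: Sequence[EqtlRecord],
    thresholds: Thresholds = Thresholds(),
) -> list[AnnotationRecord]:
    """Match catalog rows by rsID at p ≤ eqtl_p_max; one record per
    (variant, gene, tissue)."""
    by_rsid: dict[str, list[EqtlRecord]] = {}
    for rec in eqtl_catalog:
        if rec.p_value <= thresholds.eqtl_p_max:
            by_rsid.setdefault(rec.rsid, []).append(rec)
    records = []
    seen = set()
    for ev in universe:
        for rec in by_rsid.get(ev.rsid, ()):
            key = (ev.rsid, ev.region_id, rec.gene_id, rec.tissue)
            if key in seen:
                continue
            seen.add(key)
            records.append(
                AnnotationRecord(
                    ev.rsid,
                    ev.region_id,
                    "eqtl",
                    f"{rec.tissue}|{rec.gene_id}",
                    ev.is_tag_sp,
                    rec.p_value,
                )
            )
    records.sort(key=lambda r: (r.region_id, r.rsid, r.detail))
    return records


def annotate_associations(
    universe: Sequence[ExpandedVariant],
    catalog: Sequence[CatalogRecord],
    thresholds: Thresholds = Thresholds(),
) -> list[AnnotationRecord]:
    """GWAS rows kept iff p ≤ gwas_p_max (inclusive); PheWAS rows iff
    p < phewas_p_max (strict).  Unknown sources are an error."""
    by_rsid: dict[str, list[CatalogRecord]] = {}
    for rec in catalog:
        klass = _SOURCE_TO_CLASS.get(rec.source)
        if klass is None:
            raise ValueError(f"unknown catalog source {rec.source!r}")
        if klass == "gwas" and rec.p_value > thresholds.gwas_p_max:
            continue
        if klass == "phewas" and rec.p_value >= thresholds.phewas_p_max:
            continue
        by_rsid.setdefault(rec.rsid, []).append(rec)
    records = []
    seen = set()
    for ev in universe:
        for rec in by_rsid.get(ev.rsid, ()):
            klass = _SOURCE_TO_CLASS[rec.source]
            key = (ev.rsid, ev.region_id, klass, rec.trait, rec.category)
            if key in seen:
                continue
            seen.add(key)
            records.append(
                AnnotationRecord(
                    ev.rsid,
                    ev.region_id,
                    klass,
                    f"{rec.trait}|{rec.category}",
                    ev.is_tag_sp,
                    rec.p_value,
                )
            )
    records.sort(key=lambda r: (r.region_id, r.rsid, r.evidence_class, r.detail))
    return records


def annotate_all(
    universe,
    features=(),
    eqtl_catalog=(),
    catalogs=(),
    thresholds: Thresholds = Thresholds(),
) -> list[AnnotationRecord]:
    records = list(annotate_regulatory(universe, features))
    records += annotate_eqtl(universe, eqtl_catalog, thresholds)
    for catalog in catalogs:
        records += annotate_associations(universe, catalog, thresholds)
    records.sort(key=lambda r: (r.region_id, r.rsid, r.evidence_class, r.detail))
    return records


ANNOTATION_COLUMNS = ("rsid", "region_id", "evidence_class", "detail", "is_tag_sp", "p_value")


def write_annotations(path, records: Sequence[AnnotationRecord]) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for r in records:
            p = "" if r.p_value is None else f"{r.p_value:.6g}"
            out.write(
                f"{r.rsid}\t{r.region_id}\t{r.evidence_class}\t{r.detail}\t{int(r.is_tag_sp)}\t{p}\n"
            )


def read_annotations(path) -> list[AnnotationRecord]:
    from .io import _parse_table

    records = []
    for lineno, row in _parse_table(path, ANNOTATION_COLUMNS):
        try:
            records.append(
                AnnotationRecord(
                    row["rsid"],
                    row["region_id"],
                    row["evidence_class"],
                    row["detail"],
                    bool(int(row["is_tag_sp"])),
                    float(row["p_value"]) if row["p_value"] else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from None
    return records
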