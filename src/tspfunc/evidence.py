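"""Region × evidence-class summary matrix and headline counts.

A "line of functional evidence" is a distinct evidence class (regulatory,
eqtl, gwas, phewas), not a record count.  Two views are maintained: the
LD-inclusive view (a region inherits evidence carried by any member SP or
any of its LD proxies) and the SP-only view (tag SPs alone), which is a
cell-wise sub-matrix of the former.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotate import EVIDENCE_CLASSES, AnnotationRecord


@dataclass
class EvidenceMatrix:
    """Boolean region × class matrices plus per-cell supporting-record counts."""

    ld_inclusive: pd.DataFrame  # bool, index region_id, columns EVIDENCE_CLASSES
    sp_only: pd.DataFrame  # same shape, tag-SP-supported cells only
    counts_tag: pd.DataFrame  # int records from tag SPs
    counts_proxy: pd.DataFrame  # int records from LD proxies
    annotations: list[AnnotationRecord]

    @property
    def region_ids(self) -> list[str]:
        return list(self.ld_inclusive.index)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"region_id": self.region_ids})
        for klass in EVIDENCE_CLASSES:
            frame[klass] = self.ld_inclusive[klass].to_numpy().astype(int)
            frame[f"{klass}_sp_only"] = self.sp_only[klass].to_numpy().astype(int)
            frame[f"{klass}_n_tag"] = self.counts_tag[klass].to_numpy()
            frame[f"{klass}_n_proxy"] = self.counts_proxy[klass].to_numpy()
        return frame


def build_matrix(annotations: Sequence[AnnotationRecord], regions) -> EvidenceMatrix:
    """Aggregate annotation records into the region × class matrix.

    ``regions`` fixes the row universe (typically the cbSP set); a record
    referencing a region outside it is an error, never silently dropped.
    """
    region_ids = [r.region_id if hasattr(r, "region_id") else str(r) for r in regions]
    if len(set(region_ids)) != len(region_ids):
        raise ValueError("duplicate region ids in matrix row universe")
    index = pd.Index(region_ids, name="region_id")
    counts_tag = pd.DataFrame(0, index=index, columns=list(EVIDENCE_CLASSES))
    counts_proxy = pd.DataFrame(0, index=index, columns=list(EVIDENCE_CLASSES))
    known = set(region_ids)
    for rec in annotations:
        if rec.region_id not in known:
            raise ValueError(f"annotation references unknown region {rec.region_id!r}")
        target = counts_tag if rec.is_tag_sp else counts_proxy
        target.loc[rec.region_id, rec.evidence_class] += 1
    ld_inclusive = (counts_tag + counts_proxy) > 0
    sp_only = counts_tag > 0
    return EvidenceMatrix(ld_inclusive, sp_only, counts_tag, counts_proxy, list(annotations))


def summarize(matrix: EvidenceMatrix) -> dict:
    """Headline counts: regions at >= 1/2/3 evidence classes in both views,
    per-class region counts, and distinct annotated SPs / LD proxies."""
    n_classes_ld = matrix.ld_inclusive.sum(axis=1)
    n_classes_sp = matrix.sp_only.sum(axis=1)
    tag_rsids = {a.rsid for a in matrix.annotations if a.is_tag_sp}
    proxy_rsids = {a.rsid for a in matrix.annotations if not a.is_tag_sp} - tag_rsids
    summary = {
        "n_regions": len(matrix.region_ids),
        "regions_ge1": int((n_classes_ld >= 1).sum()),
        "regions_ge2": int((n_classes_ld >= 2).sum()),
        "regions_ge3": int((n_classes_ld >= 3).sum()),
        "regions_ge1_sp_only": int((n_classes_sp >= 1).sum()),
        "regions_ge2_sp_only": int((n_classes_sp >= 2).sum()),
        "regions_ge3_sp_only": int((n_classes_sp >= 3).sum()),
        "distinct_annotated_sps": len(tag_rsids),
        "distinct_annotated_proxies": len(proxy_rsids),
    }
    for klass in EVIDENCE_CLASSES:
        summary[f"regions_with_{klass}"] = int(matrix.ld_inclusive[klass].sum())
        summary[f"regions_with_{klass}_sp_only"] = int(matrix.sp_only[klass].sum())
    return summary


def write_summary(path, summary: dict) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("metric\tvalue\n")
        for key, value in summary.items():
            out.write(f"{key}\t{value}\n")
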