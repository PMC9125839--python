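"""The candidate tier cascade: SP regions -> cbSP regions -> ctSP regions.

A region is *cbSP* (candidate balanced shared polymorphism) when it carries
balancing-selection evidence from either scan: an NCD call in at least one
population, or a maximum standardized BetaScan2 score of at least
``beta_min`` (2.0).  A cbSP region is additionally *ctSP* (candidate
trans-species) when it shows evidence of identity by descent: at least
``ctsp_min_sp`` (3) clustered SPs, or a TMRCA of at least
``tmrca_min_generations`` (140,000) generations.  Both criteria at both
levels are unions (OR), and all thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core import SPRegion, Thresholds

TIERS = ("sp_only", "cbsp", "ctsp")

REASON_NCD = "ncd_call"
REASON_BETA = "beta_ge_min"
REASON_SP_COUNT = "sp_count_ge_min"
REASON_TMRCA = "tmrca_ge_min"


@dataclass(frozen=True)
class TierAssignment:
    region_id: str
    tier: str
    reasons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        cbsp_reasons = {REASON_NCD, REASON_BETA}
        idb_reasons = {REASON_SP_COUNT, REASON_TMRCA}
        if self.tier in {"cbsp", "ctsp"} and not (self.reasons & cbsp_reasons):
            raise ValueError(f"{self.region_id}: tier {self.tier} without a balancing-selection reason")
        if self.tier == "ctsp" and not (self.reasons & idb_reasons):
            raise ValueError(f"{self.region_id}: tier ctsp without an identity-by-descent reason")
        if self.tier == "sp_only" and self.reasons & cbsp_reasons:
            raise ValueError(f"{self.region_id}: sp_only with a cbSP reason recorded")


def _cbsp_reasons(region: SPRegion, thresholds: Thresholds) -> frozenset[str]:
    reasons = set()
    if region.ncd_populations:
        reasons.add(REASON_NCD)
    if region.beta_max is not None and region.beta_max >= thresholds.beta_min:
        reasons.add(REASON_BETA)
    return frozenset(reasons)


def _idb_reasons(region: SPRegion, thresholds: Thresholds) -> frozenset[str]:
    if region.tmrca_generations is not None and region.tmrca_generations < 0:
        raise ValueError(f"region {region.region_id}: negative TMRCA")
    reasons = set()
    if region.sp_count >= thresholds.ctsp_min_sp:
        reasons.add(REASON_SP_COUNT)
    if (
        region.tmrca_generations is not None
        and region.tmrca_generations >= thresholds.tmrca_min_generations
    ):
        reasons.add(REASON_TMRCA)
    return frozenset(reasons)


def classify_cbsp(
    regions: Sequence[SPRegion], thresholds: Thresholds = Thresholds()
) -> list[TierAssignment]:
    """Tier each region ``cbsp`` or ``sp_only`` on the balancing-selection
    evidence alone (absent scores are legitimate and count as no evidence)."""
    out = []
    for region in regions:
        reasons = _cbsp_reasons(region, thresholds)
        tier = "cbsp" if reasons else "sp_only"
        out.append(TierAssignment(region.region_id, tier, reasons))
    return out


def classify_ctsp(
    cbsp_regions: Sequence[SPRegion], thresholds: Thresholds = Thresholds()
) -> list[TierAssignment]:
    """Tier already-cbsp regions ``ctsp`` when the identity-by-descent
    evidence (SP count or TMRCA) also fires; otherwise they stay ``cbsp``."""
    out = []
    for region in cbsp_regions:
        cbsp = _cbsp_reasons(region, thresholds)
        if not cbsp:
            raise ValueError(f"region {region.region_id}: classify_ctsp input must already be cbsp")
        idb = _idb_reasons(region, thresholds)
        tier = "ctsp" if idb else "cbsp"
        out.append(TierAssignment(region.region_id, tier, cbsp | idb))
    return out


def classify_regions(
    regions: Sequence[SPRegion], thresholds: Thresholds = Thresholds()
) -> list[TierAssignment]:
    """Run the full cascade, returning one final TierAssignment per region."""
    out = []
    for region in regions:
        cbsp = _cbsp_reasons(region, thresholds)
        if not cbsp:
            out.append(TierAssignment(region.region_id, "sp_only", frozenset()))
            continue
        idb = _idb_reasons(region, thresholds)
        tier = "ctsp" if idb else "cbsp"
        out.append(TierAssignment(region.region_id, tier, cbsp | idb))
    return out


def tier_counts(assignments: Sequence[TierAssignment]) -> dict[str, int]:
    counts = {t: 0 for t in TIERS}
    for a in assignments:
        counts[a.tier] += 1
    return counts


def write_tiers(path, assignments: Sequence[TierAssignment]) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("region_id\ttier\treasons\n")
        for a in sorted(assignments, key=lambda x: x.region_id):
            out.write(f"{a.region_id}\t{a.tier}\t{','.join(sorted(a.reasons))}\n")
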