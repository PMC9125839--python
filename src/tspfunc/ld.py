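"""Pairwise r² from phased haplotype panels and high-LD proxy expansion.

r² between two biallelic sites is the standard haplotype-based measure:
with allele-1 frequencies p_A, p_B and joint frequency p_AB over haplotypes,
D = p_AB − p_A·p_B and r² = D² / (p_A(1−p_A) · p_B(1−p_B)).  This equals the
squared Pearson correlation of the two 0/1 indicator columns and is
invariant to swapping allele labels at either site.

Proxy expansion searches, for each tag variant, all panel variants within a
window for r² ≥ r2_min in at least one population, then unions the hits
across populations keeping the maximum r² per proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Thresholds, Variant

DEFAULT_WINDOW_BP = 500_000
POPULATIONS = ("AFR", "EAS", "EUR")


@dataclass
class HaplotypePanel:
    """A phased 0/1 haplotype matrix (rows = haplotypes, columns = variants)."""

    population: str
    variants: list[Variant]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] < 2:
            raise ValueError("panel needs at least 2 haplotypes")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.haplotypes.shape[1]} haplotype columns vs {len(self.variants)} variants"
            )
        bad = ~np.isin(self.haplotypes, (0, 1))
        if bad.any():
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def column(self, rsid: str) -> np.ndarray:
        try:
            j = next(i for i, v in enumerate(self.variants) if v.rsid == rsid)
        except StopIteration:
            raise KeyError(rsid) from None
        return self.haplotypes[:, j]


@dataclass(frozen=True)
class Proxy:
    rsid: str
    r2: float
    population: str


@dataclass
class ProxySet:
    """High-LD proxies of one tag variant, unioned across populations."""

    tag_rsid: str
    proxies: list[Proxy] = field(default_factory=list)
    populations_searched: frozenset[str] = field(default_factory=frozenset)
    found_in_panel: bool = True

    @property
    def proxy_rsids(self) -> list[str]:
        return [p.rsid for p in self.proxies]


def compute_r2(col_a: Sequence[int], col_b: Sequence[int]) -> float:
    """Haplotype-based r² between two 0/1 columns of equal length ≥ 2."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("columns must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 haplotypes")
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("undefined r2 for monomorphic site")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1.0 - p_a) * p_b * (1.0 - p_b))
    return float(min(max(r2, 0.0), 1.0))


def _r2_against_column(tag: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Vectorized r² of one column against every column of ``matrix``.

    Monomorphic columns get NaN (undefined) rather than raising.
    """
    n = tag.shape[0]
    p_a = tag.mean()
    p_b = matrix.mean(axis=0)
    p_ab = (tag[:, None] * matrix).mean(axis=0)
    denom = p_a * (1.0 - p_a) * p_b * (1.0 - p_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (p_ab - p_a * p_b) ** 2 / denom
    r2[denom == 0.0] = np.nan
    return np.clip(r2, 0.0, 1.0)


def expand_ld(
    tags: Sequence[Variant],
    panels: Sequence[HaplotypePanel],
    thresholds: Thresholds = Thresholds(),
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[ProxySet]:
    """Expand each tag variant to its r² ≥ r2_min proxy set across panels.

    A tag absent from every panel yields an empty ProxySet flagged
    ``found_in_panel=False`` (a warning record, not an error).  Panel
    variants without an rsID are excluded from proxy lists, and a tag is
    never its own proxy.  Proxies found in several populations are kept once
    with the maximum r² and the population attaining it.
    """
    searched = frozenset(p.population for p in panels)
    # Per panel: rsid -> column index, plus position arrays for windowing.
    indexes = []
    for panel in panels:
        rsid_to_col = {v.rsid: j for j, v in enumerate(panel.variants) if v.has_rsid()}
        chroms = np.array([v.chrom for v in panel.variants])
        positions = np.array([v.pos for v in panel.variants], dtype=np.int64)
        matrix = panel.haplotypes.astype(float)
        indexes.append((panel, rsid_to_col, chroms, positions, matrix))

    out: list[ProxySet] = []
    for tag in tags:
        best: dict[str, Proxy] = {}
        found = False
        for panel, rsid_to_col, chroms, positions, matrix in indexes:
            j = rsid_to_col.get(tag.rsid)
            if j is None:
                continue
            found = True
            tag_col = matrix[:, j]
            if tag_col.min() == tag_col.max():
                continue  # monomorphic in this population: no LD defined
            tag_variant = panel.variants[j]
            in_window = (
                (chroms == tag_variant.chrom)
                & (np.abs(positions - tag_variant.pos) <= window_bp)
            )
            candidate_cols = np.flatnonzero(in_window)
            if candidate_cols.size == 0:
                continue
            r2 = _r2_against_column(tag_col, matrix[:, candidate_cols])
            for k, col in enumerate(candidate_cols):
                v = panel.variants[col]
                if col == j or not v.has_rsid() or v.rsid == tag.rsid:
                    continue
                value = r2[k]
                if np.isnan(value) or value < thresholds.r2_min:
                    continue
                prev = best.get(v.rsid)
                if prev is None or value > prev.r2:
                    best[v.rsid] = Proxy(v.rsid, float(value), panel.population)
        proxies = sorted(best.values(), key=lambda p: (-p.r2, p.rsid))
        out.append(ProxySet(tag.rsid, proxies, searched, found_in_panel=found))
    return out


def write_proxies(path, proxy_sets: Sequence[ProxySet]) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("tag_rsid\tproxy_rsid\tr2\tpopulation\tfound_in_panel\n")
        for ps in sorted(proxy_sets, key=lambda s: s.tag_rsid):
            if not ps.proxies:
                out.write(f"{ps.tag_rsid}\t\t\t\t{int(ps.found_in_panel)}\n")
            for p in ps.proxies:
                out.write(f"{ps.tag_rsid}\t{p.rsid}\t{p.r2:.4f}\t{p.population}\t{int(ps.found_in_panel)}\n")
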