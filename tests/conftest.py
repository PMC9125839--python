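import numpy as np
import pytest

from tspfunc import GenomicInterval, SimConfig, SPRegion, Variant, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast, reduced-scale bundle configuration for end-to-end tests."""
    return SimConfig(
        seed=20240917,
        chrom_sizes={f"chr{i}": 3_000_000 for i in range(1, 4)},
        n_regions=40,
        n_haplotypes=60,
        n_features=1500,
        gwas_background_rows=800,
        phewas_background_rows=600,
        eqtl_background_rows=800,
        min_region_separation_bp=20_000,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_region(
    region_id="r1",
    chrom="chr1",
    positions=(1001, 2001),
    beta_max=None,
    ncd=(),
    tmrca=None,
) -> SPRegion:
    variants = [Variant(f"{region_id}_sp{i}", chrom, p) for i, p in enumerate(positions)]
    return SPRegion(
        region_id=region_id,
        interval=GenomicInterval(chrom, min(positions) - 1, max(positions)),
        sp_variants=variants,
        beta_max=beta_max,
        ncd_populations=frozenset(ncd),
        tmrca_generations=tmrca,
    )


def study_shaped_regions() -> list[SPRegion]:
    """A deterministic input shaped like the published candidate table.

    125 regions carrying 263 SPs in total: 60 regions with
    balancing-selection evidence (47 with 2 SPs, 13 with 3 SPs, i.e. 133
    SPs), of which the 13 three-SP regions plus 6 two-SP regions with
    ancient TMRCA form the trans-species subset (19 regions, 51 SPs);
    the remaining 65 regions carry 2 SPs and no scan evidence (130 SPs).
    Synthetic stand-in: coordinates and identifiers are invented, only the
    count structure follows the published breakdown.
    """
    regions = []
    i = 0

    def add(n, sp, beta, tmrca):
        nonlocal i
        for _ in range(n):
            start = 10_000 + i * 50_000
            positions = tuple(start + 100 * j for j in range(1, sp + 1))
            regions.append(
                make_region(
                    region_id=f"s{i:03d}",
                    chrom=f"chr{1 + i % 5}",
                    positions=positions,
                    beta_max=beta,
                    tmrca=tmrca,
                )
            )
            i += 1

    add(13, 3, 2.5, None)  # evidence, >= 3 SPs -> ctSP
    add(6, 2, 2.5, 150_000.0)  # evidence, ancient -> ctSP
    add(41, 2, 2.5, 50_000.0)  # evidence only -> cbSP
    add(65, 2, 1.2, 50_000.0)  # no evidence -> SP-only
    assert len(regions) == 125
    assert sum(r.sp_count for r in regions) == 263
    return regions
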