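import dataclasses
import filecmp

import numpy as np
import pytest

from tspfunc import (
    GenomicInterval,
    SimConfig,
    classify_regions,
    empirical_p,
    permutation_overlap_test,
    plant_feature_enrichment,
    simulate_dataset,
)
from tspfunc.enrichment import count_overlap_pairs
from tspfunc.filters import tier_counts


class TestDeterminism:
    def test_same_seed_same_bundle_files(self, small_config, tmp_path):
        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config)
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        paths_a = a.write(dir_a)
        paths_b = b.write(dir_b)
        for key in paths_a:
            assert filecmp.cmp(paths_a[key], paths_b[key], shallow=False), key

    def test_different_seed_differs(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a = simulate_dataset(small_config)
        b = simulate_dataset(other)
        assert [r.interval for r in a.regions] != [r.interval for r in b.regions]


class TestPlantedTiers:
    def test_no_evidence_config_yields_zero_cbsp(self):
        config = SimConfig(
            seed=1,
            n_regions=30,
            chrom_sizes={"chr1": 4_000_000},
            fraction_with_high_beta=0.0,
            fraction_with_ncd=0.0,
            n_haplotypes=20,
            n_features=200,
            min_region_separation_bp=20_000,
        )
        bundle = simulate_dataset(config)
        counts = tier_counts(classify_regions(bundle.regions))
        assert counts["cbsp"] == 0 and counts["ctsp"] == 0

    def test_disjoint_beta_and_ncd_planting_recovers_union(self):
        config = SimConfig(
            seed=5,
            n_regions=100,
            chrom_sizes={f"chr{i}": 4_000_000 for i in range(1, 9)},
            fraction_with_high_beta=0.30,
            fraction_with_ncd=0.10,
            ncd_mode="disjoint",
            n_haplotypes=20,
            n_features=200,
            min_region_separation_bp=10_000,
        )
        bundle = simulate_dataset(config)
        assignments = classify_regions(bundle.regions)
        n_cbsp_or_better = sum(1 for a in assignments if a.tier != "sp_only")
        assert n_cbsp_or_better == 40  # 30 Beta-planted + 10 disjoint NCD-planted
        truth = dict(zip(bundle.truth["region_id"], bundle.truth["true_tier"]))
        assert {a.region_id: a.tier for a in assignments} == truth


class TestPerfectLdLimit:
    def test_block_comembers_recovered_exactly(self):
        from tspfunc.ld import expand_ld

        config = SimConfig(
            seed=9,
            n_regions=10,
            chrom_sizes={"chr1": 4_000_000},
            block_r2_target=1.0,
            fraction_no_rsid=0.0,
            n_haplotypes=30,
            n_features=200,
            populations=("AFR",),
            min_region_separation_bp=60_000,
        )
        bundle = simulate_dataset(config)
        panel = bundle.panels[0]
        tags = [v for r in bundle.regions for v in r.sp_variants]
        out = expand_ld(tags, [panel])
        # block members per region share one founder: proxies == co-members
        rsid_region = {
            v.rsid: r.region_id for r in bundle.regions for v in r.sp_variants
        }
        block_members: dict[str, set] = {}
        for r in bundle.regions:
            members = {
                v.rsid
                for v in panel.variants
                if r.interval.start < v.pos <= r.interval.start + config.cluster_span_bp
                and v.has_rsid()
            }
            block_members[r.region_id] = members
        for ps in out:
            region_id = rsid_region[ps.tag_rsid]
            expected = block_members[region_id] - {ps.tag_rsid}
            got = set(ps.proxy_rsids)
            # decoy variants land in the window but are in perfect LD with
            # nothing; block co-members are at r2 == 1 by construction
            assert expected <= got
            assert all(ps_r2 == pytest.approx(1.0) for ps_r2 in [p.r2 for p in ps.proxies if p.rsid in expected])
            assert got == set(bundle.truth_proxies[ps.tag_rsid])


class TestPlantedFeatureEnrichment:
    chrom_sizes = {"chr1": 10_000_000, "chr2": 10_000_000}

    def regions(self, rng, n=50, length=4000):
        out = []
        for i in range(n):
            chrom = "chr1" if i % 2 else "chr2"
            start = int(rng.integers(0, self.chrom_sizes[chrom] - length))
            out.append(GenomicInterval(chrom, start, start + length))
        return out

    def test_fold3_realized_within_twenty_percent(self):
        rng = np.random.default_rng(17)
        regions = self.regions(rng)
        features = plant_feature_enrichment(
            regions, 3.0, 1000, 200, self.chrom_sizes, seed=rng
        )
        null = permutation_overlap_test(
            regions, [f.interval for f in features], self.chrom_sizes, n_perm=2000, seed=4
        )
        ratio = null.observed / null.null_values.mean()
        assert 2.4 <= ratio <= 3.6

    def test_fold1_with_zero_features(self):
        regions = self.regions(np.random.default_rng(1), n=5)
        features = plant_feature_enrichment(regions, 1.0, 0, 200, self.chrom_sizes, seed=0)
        assert features == []
        assert count_overlap_pairs(regions, []) == 0

    def test_excessive_density_rejected(self):
        regions = self.regions(np.random.default_rng(2), n=2)
        with pytest.raises(ValueError, match="density"):
            plant_feature_enrichment(
                regions, 1.0, 100_000, 1000, {"chr1": 1_000_000, "chr2": 1_000_000}, seed=0
            )

    def test_features_avoid_exclusions(self):
        exclusions = [GenomicInterval("chr1", 0, 9_000_000)]
        regions = [GenomicInterval("chr1", 9_100_000, 9_104_000)]
        rng = np.random.default_rng(3)
        features = plant_feature_enrichment(
            regions, 2.0, 300, 200, {"chr1": 10_000_000}, exclusions, seed=rng
        )
        # midpoints are drawn outside the exclusion zone
        assert all(f.interval.end > 9_000_000 - 100 for f in features)


class TestInfeasibleConfigs:
    def test_regions_must_fit_genome(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_dataset(
                SimConfig(seed=0, n_regions=100, chrom_sizes={"chr1": 100_000})
            )


class TestClusterInvariants:
    def test_sps_clustered_within_4kb(self, small_bundle):
        for region in small_bundle.regions:
            assert region.sp_count >= 2
            assert region.interval.length <= small_bundle.config.cluster_span_bp
            for v in region.sp_variants:
                assert region.interval.contains_pos(v.pos)

    def test_regions_avoid_exclusions(self, small_bundle):
        for region in small_bundle.regions:
            for ex in small_bundle.exclusions:
                assert not (
                    ex.chrom == region.interval.chrom
                    and region.interval.start < ex.end
                    and ex.start < region.interval.end
                )
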