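import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tspfunc import HaplotypePanel, Thresholds, Variant, compute_r2, expand_ld


def haplotype_column(draw_fn, n):
    return draw_fn(st.lists(st.integers(0, 1), min_size=n, max_size=n))


class TestComputeR2:
    def test_identical_columns_give_one(self):
        col = [0, 1, 0, 1, 1, 0]
        assert compute_r2(col, col) == pytest.approx(1.0)

    def test_hand_counted_example(self):
        """Four (1,1), four (0,0), two (1,0) haplotypes: r2 = 4/9."""
        a = [1, 1, 1, 1, 0, 0, 0, 0, 1, 1]
        b = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        assert compute_r2(a, b) == pytest.approx(4.0 / 9.0, rel=1e-12)

    def test_complementary_columns_give_one(self):
        a = np.array([0, 1, 1, 0, 1])
        assert compute_r2(a, 1 - a) == pytest.approx(1.0)

    def test_monomorphic_column_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_r2([0, 0, 0], [0, 1, 0])

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_equals_squared_pearson_correlation(self, data):
        n = data.draw(st.integers(4, 40))
        a = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        b = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if a.min() == a.max() or b.min() == b.max():
            return
        expected = float(np.corrcoef(a, b)[0, 1]) ** 2
        assert compute_r2(a, b) == pytest.approx(expected, abs=1e-12)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_label_swap_invariance(self, data):
        n = data.draw(st.integers(4, 30))
        a = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        b = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if a.min() == a.max() or b.min() == b.max():
            return
        r = compute_r2(a, b)
        assert compute_r2(b, a) == pytest.approx(r)
        assert compute_r2(1 - a, b) == pytest.approx(r)
        assert compute_r2(a, 1 - b) == pytest.approx(r)


def two_block_panel(population="AFR", n_hap=20):
    """Two perfect-LD blocks of 3 variants each plus one independent site."""
    rng = np.random.default_rng(7)
    block1 = (rng.random(n_hap) < 0.5).astype(np.int8)
    block2 = (rng.random(n_hap) < 0.5).astype(np.int8)
    indep = np.zeros(n_hap, dtype=np.int8)
    indep[: n_hap // 2] = 1
    rng.shuffle(indep)
    variants = [
        Variant("tag1", "chr1", 1000),
        Variant("b1a", "chr1", 1100),
        Variant("b1b", "chr1", 1200),
        Variant("tag2", "chr1", 5000),
        Variant("b2a", "chr1", 5100),
        Variant(".", "chr1", 5200),  # no rsID: never reported as a proxy
        Variant("lonely", "chr1", 9000),
    ]
    columns = [block1, block1, block1, block2, block2, block2, indep]
    return HaplotypePanel(population, variants, np.array(columns).T)


class TestExpandLd:
    def test_perfect_blocks_recovered_exactly(self):
        panel = two_block_panel()
        out = expand_ld([Variant("tag1", "chr1", 1000), Variant("tag2", "chr1", 5000)], [panel])
        by_tag = {ps.tag_rsid: ps for ps in out}
        assert sorted(by_tag["tag1"].proxy_rsids) == ["b1a", "b1b"]
        # the no-rsID block member is excluded even at r2 = 1
        assert sorted(by_tag["tag2"].proxy_rsids) == ["b2a"]
        assert all(p.r2 == pytest.approx(1.0) for p in by_tag["tag1"].proxies)

    def test_tag_never_its_own_proxy(self):
        panel = two_block_panel()
        out = expand_ld([Variant("tag1", "chr1", 1000)], [panel])
        assert "tag1" not in out[0].proxy_rsids

    def test_absent_tag_is_warning_record(self):
        panel = two_block_panel()
        out = expand_ld([Variant("rs_missing", "chr1", 1234)], [panel])
        assert out[0].found_in_panel is False
        assert out[0].proxies == []

    def test_window_limits_search(self):
        panel = two_block_panel()
        out = expand_ld([Variant("tag1", "chr1", 1000)], [panel], window_bp=150)
        assert sorted(out[0].proxy_rsids) == ["b1a"]

    def test_raising_r2_min_never_grows_proxy_sets(self, rng):
        n_hap, n_var = 40, 12
        cols = (rng.random((n_hap, n_var)) < rng.uniform(0.2, 0.8, n_var)).astype(np.int8)
        cols[:, 0] = cols[:, 1]  # guarantee one perfect pair
        variants = [Variant(f"v{j}", "chr1", 100 + j * 10) for j in range(n_var)]
        panel = HaplotypePanel("EUR", variants, cols)
        tags = [variants[0], variants[5]]
        sizes = []
        for r2_min in (0.2, 0.5, 0.8, 0.95):
            out = expand_ld(tags, [panel], Thresholds(r2_min=r2_min))
            sizes.append([set(ps.proxy_rsids) for ps in out])
        for loose, tight in zip(sizes, sizes[1:]):
            for a, b in zip(loose, tight):
                assert b <= a

    def test_union_across_populations_keeps_max_r2(self):
        n = 20
        rng = np.random.default_rng(3)
        base = (rng.random(n) < 0.5).astype(np.int8)
        noisy = base.copy()
        noisy[:2] ^= 1  # imperfect LD in population A
        variants = [Variant("tag", "chr1", 100), Variant("prox", "chr1", 200)]
        panel_a = HaplotypePanel("AFR", variants, np.array([base, noisy]).T)
        panel_b = HaplotypePanel("EUR", variants, np.array([base, base]).T)
        out = expand_ld([variants[0]], [panel_a, panel_b])[0]
        assert len(out.proxies) == 1
        assert out.proxies[0].r2 == pytest.approx(1.0)
        assert out.proxies[0].population == "EUR"
        assert out.populations_searched == {"AFR", "EUR"}


class TestHaplotypePanel:
    def test_rejects_non_binary_entries(self):
        with pytest.raises(ValueError, match="0/1"):
            HaplotypePanel("AFR", [Variant("a", "chr1", 1)], np.array([[2], [0]]))

    def test_rejects_single_haplotype(self):
        with pytest.raises(ValueError, match="2 haplotypes"):
            HaplotypePanel("AFR", [Variant("a", "chr1", 1)], np.array([[1]]))
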