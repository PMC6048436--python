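"""Fold-enrichment arithmetic and circular-permutation nulls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolgea import (
    adjust_enrichment_fdr,
    circular_permutation_test,
    fold_enrichment_annotation,
    fold_enrichment_xtx,
    upper_tail,
)
from poolgea.datamodel import ValidationError
from poolgea.enrichment import EnrichmentResult, _circular_overlap


class TestUpperTail:
    def test_floor_of_fraction(self):
        vals = np.arange(1000, dtype=float)
        assert len(upper_tail(vals, 0.005)) == 5

    def test_large_scale_floor(self):
        # 0.5% of 1,638,649 values -> 8,193 by floor rounding
        assert int(np.floor(0.005 * 1_638_649)) == 8193

    def test_selects_largest(self):
        vals = np.array([3.0, 9.0, 1.0, 7.0, 5.0, 8.0, 2.0, 6.0, 4.0, 0.0])
        idx = upper_tail(vals, 0.3)
        assert sorted(vals[idx]) == [7.0, 8.0, 9.0]

    def test_tie_break_by_genome_order(self):
        vals = np.ones(10)
        idx = upper_tail(vals, 0.5)
        assert idx.tolist() == [0, 1, 2, 3, 4]

    def test_errors(self):
        with pytest.raises(ValidationError):
            upper_tail(np.array([]), 0.1)
        with pytest.raises(ValidationError):
            upper_tail(np.ones(5), 1.5)


class TestFoldEnrichment:
    def test_annotation_hand_example(self):
        # s = 200 tail SNPs of which s_a = 40 in category; genome
        # S = 10,000 with S_a = 1,000 -> FE = (40/200)/(1000/10000) = 2.0
        cats = np.array(
            ["replacement"] * 1000 + ["intergenic"] * 9000, dtype=object
        )
        top = np.concatenate([np.arange(40), np.arange(1000, 1160)])
        r = fold_enrichment_annotation(top, cats, "replacement")
        assert r.fold_enrichment == pytest.approx(2.0, abs=1e-12)
        assert (r.tail_size, r.tail_hits, r.total, r.total_hits) == (
            200, 40, 10_000, 1000,
        )

    def test_random_tail_is_unenriched(self):
        rng = np.random.default_rng(0)
        cats = np.array(
            ["intron" if x < 0.3 else "intergenic" for x in rng.random(20_000)],
            dtype=object,
        )
        top = rng.choice(20_000, size=2000, replace=False)
        r = fold_enrichment_annotation(top, cats, "intron")
        assert r.fold_enrichment == pytest.approx(1.0, abs=0.1)

    def test_xtx_hand_example(self):
        # both tails 50 of 10,000; overlap 10 -> FE = (10/50)/(50/10000) = 40
        top_bf = np.arange(50)
        top_xtx = np.concatenate([np.arange(10), np.arange(100, 140)])
        r = fold_enrichment_xtx(top_bf, top_xtx, 10_000)
        assert r.fold_enrichment == pytest.approx(40.0, abs=1e-12)

    def test_independent_tails_near_one(self):
        rng = np.random.default_rng(1)
        n = 50_000
        a = rng.choice(n, size=2500, replace=False)
        b = rng.choice(n, size=2500, replace=False)
        r = fold_enrichment_xtx(a, b, n)
        assert r.fold_enrichment == pytest.approx(1.0, abs=0.25)

    def test_undefined_flagged(self):
        cats = np.array(["intron"] * 10, dtype=object)
        r = fold_enrichment_annotation(np.arange(2), cats, "UTR")
        assert r.undefined and np.isnan(r.fold_enrichment)

    def test_category_counts_partition_the_tail(self):
        rng = np.random.default_rng(2)
        cats = rng.choice(
            np.array(["intron", "UTR", "intergenic"], dtype=object), size=500
        )
        top = rng.choice(500, size=50, replace=False)
        s_a = sum(
            fold_enrichment_annotation(top, cats, c).tail_hits
            for c in ["intron", "UTR", "intergenic"]
        )
        assert s_a == 50


class TestCircularPermutation:
    def test_zero_offset_reproduces_observed(self):
        rng = np.random.default_rng(3)
        tail = rng.random(200) < 0.1
        attr = rng.random(200) < 0.4
        obs = ((tail & attr).sum() / tail.sum()) / (attr.sum() / 200)
        overlap0 = _circular_overlap(tail, attr, np.array([0]))[0]
        fe0 = (overlap0 / tail.sum()) / (attr.sum() / 200)
        assert fe0 == pytest.approx(obs, abs=1e-12)

    def test_exhaustive_matches_roll_oracle(self):
        # brute-force oracle on a <= 20-SNP instance: every rotation offset
        rng = np.random.default_rng(4)
        tail = rng.random(18) < 0.3
        attr = rng.random(18) < 0.5
        tail[0] = attr[0] = True  # guard against degenerate all-false draws
        _, null = circular_permutation_test(tail, attr, exhaustive=True)
        expect = []
        n, s, Sa = 18, tail.sum(), attr.sum()
        for o in range(1, 18):
            ov = (np.roll(tail, o) & attr).sum()
            expect.append((ov / s) / (Sa / n))
        np.testing.assert_allclose(null, expect, atol=1e-12)

    def test_invariant_to_joint_rotation(self):
        rng = np.random.default_rng(5)
        tail = rng.random(300) < 0.1
        attr = rng.random(300) < 0.3
        tail[:3] = attr[:3] = True
        p1, _ = circular_permutation_test(tail, attr, n_perm=500, seed=9)
        shift = 123
        p2, _ = circular_permutation_test(
            np.roll(tail, shift), np.roll(attr, shift), n_perm=500, seed=9
        )
        assert p1 == p2

    def test_add_one_estimator_never_zero(self):
        tail = np.zeros(50, dtype=bool)
        tail[:5] = True
        attr = np.zeros(50, dtype=bool)
        attr[:5] = True  # perfectly aligned: maximal enrichment
        p, null = circular_permutation_test(tail, attr, n_perm=200, seed=1)
        assert p == pytest.approx(1 / 201, abs=1e-12)

    def test_clustered_rotation_null_wider_than_shuffle(self):
        # rotation preserves runs; against a clustered attribute this
        # yields a wider null than independent shuffling of SNPs
        rng = np.random.default_rng(6)
        n = 1000
        tail = np.zeros(n, dtype=bool)
        tail[100:150] = True            # one clustered tail
        attr = np.zeros(n, dtype=bool)
        attr[400:600] = True            # one clustered category
        _, rot_null = circular_permutation_test(
            tail, attr, n_perm=2000, seed=7
        )
        shuf = []
        for _ in range(2000):
            sh = rng.permutation(tail)
            shuf.append(
                ((sh & attr).sum() / tail.sum()) / (attr.sum() / n)
            )
        assert rot_null.var() > 2.0 * np.var(shuf)

    def test_null_pvalues_uniform_under_no_enrichment(self):
        # calibration: independent tail and attribute, 200 replicates
        rng = np.random.default_rng(8)
        n = 2000
        pvals = []
        for _ in range(200):
            scores = rng.standard_normal(n)
            tail = np.zeros(n, dtype=bool)
            tail[upper_tail(scores, 0.10)] = True
            attr = rng.random(n) < 0.4
            p, _ = circular_permutation_test(
                tail, attr, n_perm=499, seed=int(rng.integers(2**31))
            )
            pvals.append(p)
        from scipy import stats

        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestFdrAdjustment:
    def _res(self, p):
        r = EnrichmentResult(
            covariate="c", category="intron", tail_size=10, tail_hits=5,
            total=100, total_hits=20, fold_enrichment=2.5,
        )
        r.p_perm = p
        return r

    def test_single_test_unchanged(self):
        rs = adjust_enrichment_fdr([self._res(0.037)])
        assert rs[0].fdr_adjusted_p == pytest.approx(0.037)

    def test_hand_bh_example(self):
        rs = adjust_enrichment_fdr([self._res(p) for p in (0.01, 0.02, 0.03, 0.04)])
        np.testing.assert_allclose(
            [r.fdr_adjusted_p for r in rs], [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_one(self):
        rs = adjust_enrichment_fdr([self._res(1.0) for _ in range(5)])
        assert all(r.fdr_adjusted_p == 1.0 for r in rs)


@settings(deadline=None, max_examples=50)
@given(
    n=st.integers(min_value=10, max_value=300),
    frac=st.floats(min_value=0.01, max_value=0.99),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_upper_tail_size_and_membership_property(n, frac, seed):
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal(n)
    idx = upper_tail(vals, frac)
    k = int(np.floor(frac * n))
    assert len(idx) == k
    if k:
        assert vals[idx].min() >= np.sort(vals)[::-1][:k].min() - 1e-12
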