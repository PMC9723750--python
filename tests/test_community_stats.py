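"""Community statistics against hand calculations, enumeration oracles, and skbio."""

import itertools

import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import given, settings
from hypothesis import strategies as st

from mycospat.community_stats import (
    DistanceMatrix,
    bh_fdr,
    bray_curtis,
    classify_host_specificity,
    cophenetic_distance,
    define_core_otus,
    gower_distance,
    mantel,
    permanova,
    rarefy,
)


class TestRarefy:
    def test_full_depth_identity(self):
        row = np.array([3, 0, 7, 5])
        out = rarefy(row, 15, seed=0)
        np.testing.assert_array_equal(out, row)

    def test_zeros_stay_zero_and_total_exact(self):
        out = rarefy(np.array([5, 0, 5]), 4, seed=1)
        assert out.sum() == 4 and out[1] == 0

    def test_depth_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            rarefy(np.array([1, 1]), 5, seed=0)

    def test_hypergeometric_expectation(self):
        """Mean rarefied count matches depth * c_k / total within 3 s.e."""
        row = np.array([60, 30, 10])
        depth, n_draw = 40, 2000
        rng = np.random.default_rng(7)
        draws = np.array([rarefy(row, depth, rng) for _ in range(n_draw)])
        total = row.sum()
        expected = depth * row / total
        # hypergeometric variance per category
        var = depth * (row / total) * (1 - row / total) * (total - depth) / (total - 1)
        se = np.sqrt(var / n_draw)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9)


class TestBrayCurtis:
    def test_hand_formula(self):
        m = pd.DataFrame([[6, 2, 0], [2, 2, 4]], index=["x", "y"])
        assert bray_curtis(m)["x", "y"] == pytest.approx(0.5, abs=1e-12)

    def test_identity_and_disjoint_limits(self):
        m = pd.DataFrame([[1, 2, 0], [1, 2, 0], [0, 0, 9]], index=list("abc"))
        d = bray_curtis(m)
        assert d["a", "b"] == 0
        assert d["a", "c"] == pytest.approx(1.0)

    def test_all_zero_row_named_in_error(self):
        m = pd.DataFrame([[1, 2], [0, 0]], index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(m)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_range_symmetry_hollow(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.integers(1, 50, size=(5, 8)))
        d = bray_curtis(m).data
        assert np.all(d >= 0) and np.all(d <= 1)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


def _dm(mat, labels=None):
    mat = np.asarray(mat, dtype=float)
    labels = labels or [f"e{k}" for k in range(len(mat))]
    return DistanceMatrix(labels, mat)


class TestPermanova:
    def _toy(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2, 1, (3, 2))])
        from scipy.spatial.distance import pdist, squareform

        return _dm(squareform(pdist(pts)))

    def test_exhaustive_matches_independent_enumeration(self):
        """Exact p over all 20 distinct 3+3 labelings equals a direct-formula oracle."""
        dm = self._toy()
        groups = ["g1"] * 3 + ["g2"] * 3
        res = permanova(dm, groups, exhaustive=True)

        def oracle_f(lab):
            d2 = dm.data**2
            n, a = 6, 2
            ss_t = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
            ss_w = 0.0
            for g in ("g1", "g2"):
                idx = [k for k in range(n) if lab[k] == g]
                ss_w += sum(
                    d2[i, j] for i in idx for j in idx if i < j
                ) / len(idx)
            return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))

        f_obs = oracle_f(groups)
        fs = []
        for combo in itertools.combinations(range(6), 3):
            lab = ["g2"] * 6
            for c in combo:
                lab[c] = "g1"
            fs.append(oracle_f(lab))
        p_oracle = sum(1 for f in fs if f >= f_obs - 1e-12) / len(fs)
        assert res.pseudo_f == pytest.approx(f_obs, rel=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-15)
        assert res.n_perm == 20

    def test_statistic_agrees_with_skbio(self):
        """Pseudo-F matches the independent PERMANOVA implementation in skbio."""
        dm = self._toy()
        groups = ["g1"] * 3 + ["g2"] * 3
        ours = permanova(dm, groups, n_perm=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, ids=dm.labels), grouping=groups,
            permutations=99,
        )
        assert ours.pseudo_f == pytest.approx(float(theirs["test statistic"]), rel=1e-10)

    def test_exchangeable_distances_give_p_one(self):
        d = np.ones((6, 6)) - np.eye(6)
        res = permanova(_dm(d), ["a"] * 3 + ["b"] * 3, exhaustive=True)
        assert res.p_value == 1.0

    def test_perfect_separation_gives_inf_sentinel(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = 1.0
        d[3:, :3] = 1.0
        res = permanova(_dm(d), ["a"] * 3 + ["b"] * 3, exhaustive=True)
        assert np.isinf(res.pseudo_f)
        assert res.p_value == pytest.approx(2 / 20)  # the two perfect splits

    def test_group_size_validation(self):
        dm = self._toy()
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 5 + ["b"], n_perm=9)
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 6, n_perm=9)


class TestMantel:
    def _pair(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.uniform(1, 5, (5, 5))
        a = np.triu(a, 1)
        a = a + a.T
        b = a + rng.uniform(0, 1, (5, 5))
        b = np.triu(b, 1)
        b = b + b.T
        return _dm(a), _dm(b)

    def test_self_correlation_is_one(self):
        d1, _ = self._pair()
        r, _ = mantel(d1, d1, n_perm=19, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self):
        d1, _ = self._pair()
        d2 = _dm(2.0 * d1.data + 3.0 * (1 - np.eye(5)))
        r, _ = mantel(d1, d2, n_perm=19, seed=0)
        assert r == pytest.approx(1.0)

    def test_exhaustive_matches_permutation_enumeration(self):
        """Exact p equals enumeration of all 120 simultaneous permutations."""
        d1, d2 = self._pair(4)
        r_obs, p = mantel(d1, d2, exhaustive=True)
        x = d1.condensed()
        rs = []
        for perm in itertools.permutations(range(5)):
            pm = np.array(perm)
            y = d2.data[np.ix_(pm, pm)]
            from scipy.spatial.distance import squareform

            rs.append(np.corrcoef(x, squareform(y, checks=False))[0, 1])
        p_oracle = sum(1 for r in rs if r >= r_obs - 1e-12) / len(rs)
        assert p == pytest.approx(p_oracle, abs=1e-15)

    def test_r_agrees_with_skbio(self):
        d1, d2 = self._pair(8)
        r, _ = mantel(d1, d2, n_perm=19, seed=0)
        r_skbio, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(d1.data), skbio.DistanceMatrix(d2.data),
            permutations=0,
        )
        assert r == pytest.approx(float(r_skbio), rel=1e-10)

    def test_zero_variance_rejected(self):
        d1, _ = self._pair()
        flat = _dm(np.ones((5, 5)) - np.eye(5))
        with pytest.raises(ValueError, match="undefined correlation"):
            mantel(d1, flat, n_perm=9)


class TestBHFDR:
    def test_hand_step_up_case(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_never_below_raw_and_idempotent_safe(self, pvals):
        adj = bh_fdr(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(bh_fdr(adj) >= adj - 1e-12)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestGower:
    def test_hand_mixed_table(self):
        t = pd.DataFrame(
            {"height": [10.0, 20.0, 30.0], "type": ["a", "a", "b"]},
            index=["s1", "s2", "s3"],
        )
        d = gower_distance(t)
        # numeric range 20; (|10-20|/20 + 0)/2 = 0.25
        assert d["s1", "s2"] == pytest.approx(0.25)
        assert d["s1", "s3"] == pytest.approx((1.0 + 1.0) / 2)
        assert d["s2", "s3"] == pytest.approx((0.5 + 1.0) / 2)

    def test_identity_and_extremes(self):
        t = pd.DataFrame({"x": [0.0, 0.0, 10.0]}, index=list("abc"))
        d = gower_distance(t)
        assert d["a", "b"] == 0
        assert d["a", "c"] == 1.0

    def test_missing_values_pairwise_deleted(self):
        t = pd.DataFrame(
            {"x": [1.0, np.nan, 3.0], "y": [0.0, 2.0, 4.0]}, index=list("abc")
        )
        d = gower_distance(t)
        # (a, b): only y observed jointly -> |0-2|/4 = 0.5
        assert d["a", "b"] == pytest.approx(0.5)

    def test_no_jointly_observed_trait_rejected(self):
        t = pd.DataFrame({"x": [1.0, np.nan], "y": [np.nan, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            gower_distance(t)


class TestCophenetic:
    def test_toy_tree_path_sums(self):
        d = cophenetic_distance("((A:1,B:1):1,C:2);")
        assert d["A", "B"] == pytest.approx(2.0)
        assert d["A", "C"] == pytest.approx(4.0)
        assert d["B", "C"] == pytest.approx(4.0)
        assert d["A", "A"] == 0

    def test_star_tree_equal_branches(self):
        d = cophenetic_distance("(A:3,B:3,C:3,D:3);")
        off = d.data[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 6.0)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError):
            cophenetic_distance("((A:1,A:1):1,C:2);")


class TestCoreOTUs:
    def _table(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(0, 4, size=(8, 30)),
                         columns=[f"o{k}" for k in range(30)])
        return t

    def test_half_detection_is_core_at_half_cutoff(self):
        t = pd.DataFrame(0, index=range(8), columns=["a", "b"])
        t.loc[:3, "a"] = 5  # 4 of 8 samples
        t.loc[0, "b"] = 1   # 1 of 8
        cs = define_core_otus(t, 0.5, species="sp")
        assert "a" in cs.otus and "b" not in cs.otus

    def test_seven_of_eight_not_core_at_09(self):
        t = pd.DataFrame(0, index=range(8), columns=["a"])
        t.loc[:6, "a"] = 2  # 7 of 8 = 0.875
        assert "a" not in define_core_otus(t, 0.9).otus

    def test_nesting_and_coverage_monotone_across_cutoffs(self):
        t = self._table()
        prev = None
        prev_cov = None
        for c in [0.1 * k for k in range(1, 10)]:
            cs = define_core_otus(t, c)
            # brute-force membership check at this cutoff
            freq = (t > 0).mean(axis=0)
            expected = {o for o in t.columns if freq[o] >= c - 1e-12}
            assert cs.otus == frozenset(expected)
            if prev is not None:
                assert cs.otus <= prev
                assert cs.coverage <= prev_cov + 1e-12
            prev, prev_cov = cs.otus, cs.coverage

    def test_cutoff_domain(self):
        with pytest.raises(ValueError):
            define_core_otus(self._table(), 0.0)


class TestHostSpecificity:
    @pytest.mark.parametrize(
        "k,call",
        [(38, "host-specific"), (35, "host-dependent"), (34, "nonspecific"),
         (37, "host-dependent"), (0, "nonspecific")],
    )
    def test_rule_over_38_comparisons(self, k, call):
        p = np.concatenate([np.full(k, 0.001), np.full(38 - k, 0.5)])
        assert classify_host_specificity(p).call == call

    def test_specific_implies_dependent_threshold(self):
        res = classify_host_specificity(np.full(10, 0.001))
        assert res.call == "host-specific"
        assert res.n_significant >= int(np.ceil(0.9 * res.n_compared))
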