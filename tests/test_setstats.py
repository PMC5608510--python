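"""Overlap, directionality, correlation and clustering statistics."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from coregdep import (
    SignedGeneSet,
    cluster_genes,
    combine_pairs,
    directionality_consistency,
    effect_correlation,
    hypergeometric_overlap,
    pairwise_overlap_matrix,
)


def _set(label, inc=(), dec=()):
    return SignedGeneSet(
        label, {**{g: "increased" for g in inc}, **{g: "decreased" for g in dec}}
    )


def exact_upper_tail(N, K, n, k):
    """Exhaustive-draw hypergeometric tail P(X >= k) as an exact rational."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return float(acc)


class TestHypergeometricOverlap:
    UNIVERSE = [f"g{i}" for i in range(10)]

    def test_zero_overlap_is_one(self):
        st = hypergeometric_overlap({"g0"}, {"g1"}, self.UNIVERSE)
        assert st.p_value == 1.0

    def test_full_universe_set_is_one(self):
        st = hypergeometric_overlap(set(self.UNIVERSE), {"g1", "g2"}, self.UNIVERSE)
        assert st.p_value == pytest.approx(1.0)

    def test_counting_example(self):
        # N=10, K=4, n=5, k=3 -> 66 favorable draws of C(10,5)=252
        a = {"g0", "g1", "g2", "g3"}
        b = {"g0", "g1", "g2", "g4", "g5"}
        st = hypergeometric_overlap(a, b, self.UNIVERSE)
        assert (st.N, st.K, st.n, st.k) == (10, 4, 5, 3)
        assert st.p_value == pytest.approx(66 / 252, abs=1e-12)

    def test_member_outside_universe_listed(self):
        with pytest.raises(ValueError, match="gX"):
            hypergeometric_overlap({"gX"}, {"g1"}, self.UNIVERSE)

    def test_matches_enumeration_on_spot_checks(self):
        for N, K, n, k in [(12, 5, 6, 2), (15, 7, 7, 5), (8, 3, 3, 0), (9, 9, 4, 4)]:
            universe = [f"u{i}" for i in range(N)]
            a = set(universe[:K])
            b = set(universe[: k]) | set(universe[K : K + n - k])
            st = hypergeometric_overlap(a, b, universe)
            assert st.k == k
            assert st.p_value == pytest.approx(exact_upper_tail(N, K, n, k), abs=1e-12)


class TestPairwiseOverlapMatrix:
    def _random_sets(self, m, rng):
        universe = [f"g{i}" for i in range(60)]
        sets = []
        for i in range(m):
            members = rng.choice(universe, size=rng.integers(5, 25), replace=False)
            tags = rng.choice(["increased", "decreased"], size=len(members))
            sets.append(SignedGeneSet(f"s{i}", dict(zip(members, tags))))
        return sets, universe

    def test_seventeen_sets_give_136_pairs(self):
        rng = np.random.default_rng(0)
        sets, universe = self._random_sets(17, rng)
        ov = pairwise_overlap_matrix(sets, universe)
        assert ov.n_pairs == 136

    def test_two_sets_one_pair(self):
        rng = np.random.default_rng(1)
        sets, universe = self._random_sets(2, rng)
        assert pairwise_overlap_matrix(sets, universe).n_pairs == 1

    def test_cells_match_direct_calls_and_symmetry(self):
        rng = np.random.default_rng(2)
        sets, universe = self._random_sets(3, rng)
        ov = pairwise_overlap_matrix(sets, universe)
        for sa, sb in combinations(sets, 2):
            st = hypergeometric_overlap(sa, sb, universe)
            assert ov.counts.loc[sa.label, sb.label] == st.k
            assert ov.p_values.loc[sa.label, sb.label] == pytest.approx(st.p_value)
        pd.testing.assert_frame_equal(ov.counts, ov.counts.T)
        for s in sets:
            assert ov.counts.loc[s.label, s.label] == len(s)

    def test_duplicate_labels_rejected(self):
        a = _set("same", inc=["g0"])
        b = _set("same", inc=["g1"])
        with pytest.raises(ValueError, match="duplicate"):
            pairwise_overlap_matrix([a, b], ["g0", "g1"])


class TestDirectionalityConsistency:
    def test_half_consistent_example(self):
        a = _set("A", inc=["x", "y"])
        b = SignedGeneSet("B", {"x": "increased", "y": "decreased"})
        out = directionality_consistency(a, b)
        assert out["a_increased_in_b_pct"] == pytest.approx(50.0)

    def test_identical_sets_fully_consistent(self):
        a = _set("A", inc=["x", "y"], dec=["z"])
        out = directionality_consistency(a, SignedGeneSet("B", dict(a.directions)))
        for key in (
            "a_increased_in_b_pct", "b_increased_in_a_pct",
            "a_decreased_in_b_pct", "b_decreased_in_a_pct",
        ):
            assert out[key] == pytest.approx(100.0)
        assert out["opposite"] == 0

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(50)]

        def random_set(label):
            members = rng.choice(genes, size=30, replace=False)
            tags = rng.choice(["increased", "decreased"], size=30)
            return SignedGeneSet(label, dict(zip(members, tags)))

        a, b = random_set("A"), random_set("B")
        out = directionality_consistency(a, b)
        inter = a.members & b.members
        assert out["overlap"] == len(inter)
        denom = [g for g in inter if a.directions[g] == "increased"]
        num = [g for g in denom if b.directions[g] == "increased"]
        assert out["a_increased_in_b_pct"] == pytest.approx(100 * len(num) / len(denom))
        assert out["consistent"] + out["opposite"] == len(inter)


class TestEffectCorrelation:
    def test_identical_and_negated_columns(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        m = pd.DataFrame({"a": x, "b": x, "c": -x})
        corr = effect_correlation(m)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("wxyz"))
        corr = effect_correlation(m)
        ref = np.corrcoef(m.to_numpy(), rowvar=False)
        np.testing.assert_allclose(corr.to_numpy(), ref, atol=1e-12)

    def test_zero_variance_column_warned_and_zeroed(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10), "c": rng.normal(size=10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = effect_correlation(m)
        assert corr.loc["a", "b"] == 0.0
        assert corr.loc["b", "b"] == 1.0


class TestCombinePairs:
    def _sets_and_corr(self):
        sets = [
            _set("a", inc=["g1", "g2"]),
            SignedGeneSet("b", {"g2": "decreased", "g3": "increased"}),
            _set("c", inc=["g4"]),
        ]
        corr = pd.DataFrame(
            [[1.0, 0.8, 0.1], [0.8, 1.0, 0.3], [0.1, 0.3, 1.0]],
            index=["a", "b", "c"], columns=["a", "b", "c"],
        )
        return sets, corr

    def test_merge_keeps_consistent_tags_only(self):
        sets, corr = self._sets_and_corr()
        merged = combine_pairs(corr, sets, r_min=0.25)
        assert [(la, lb) for la, lb, _, _ in merged] == [("a", "b"), ("b", "c")]
        top = merged[0][3]
        assert top.members == {"g1", "g2", "g3"}
        assert top.directions["g1"] == "increased"
        assert top.directions["g2"] is None  # conflicting tags dropped

    def test_invariant_to_column_reordering(self):
        sets, corr = self._sets_and_corr()
        ref = combine_pairs(corr, sets, r_min=0.25)
        shuffled = corr.loc[["c", "a", "b"], ["b", "c", "a"]]
        got = combine_pairs(shuffled, sets, r_min=0.25)
        assert [(m[0], m[1], m[2]) for m in got] == [(m[0], m[1], m[2]) for m in ref]
        assert [dict(m[3].directions) for m in got] == [dict(m[3].directions) for m in ref]


def _bruteforce_average_linkage(dist):
    """Independent agglomeration trace: returns sorted merge heights."""
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)


class TestClusterGenes:
    def test_identical_profiles_merge_first_at_zero(self):
        m = pd.DataFrame(
            [[1, 0, -1], [1, 0, -1], [-1, 1, 0], [0, -1, 1]],
            index=["a", "b", "c", "d"],
        )
        res = cluster_genes(m)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        first = {int(res.linkage[0, 0]), int(res.linkage[0, 1])}
        assert first == {0, 1}  # the identical pair

    def test_row_permutation_gives_same_tree(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(8, 5)), index=[f"g{i}" for i in range(8)])
        ref = cluster_genes(m)
        perm = rng.permutation(8)
        got = cluster_genes(m.iloc[perm])
        np.testing.assert_allclose(
            sorted(got.linkage[:, 2]), sorted(ref.linkage[:, 2]), atol=1e-12
        )

    def test_merge_heights_match_manual_agglomeration(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"g{i}" for i in range(6)])
        res = cluster_genes(m)
        corr = np.corrcoef(m.to_numpy())
        dist = 1 - corr
        np.fill_diagonal(dist, 0.0)
        np.testing.assert_allclose(
            sorted(res.linkage[:, 2]), _bruteforce_average_linkage(dist), atol=1e-10
        )

    def test_constant_profile_flagged(self):
        m = pd.DataFrame(
            [[1, 1, 1], [1, 0, -1], [0, 1, -1]], index=["flat", "a", "b"]
        )
        res = cluster_genes(m)
        assert res.constant_profiles == ["flat"]

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(size=(5, 4)), index=[f"g{i}" for i in range(5)])
        res = cluster_genes(m)
        assert res.newick.endswith(";")
        for g in m.index:
            assert g in res.newick
        assert sorted(res.leaf_order) == sorted(m.index)
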