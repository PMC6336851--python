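import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_entity, random_geneset, random_ranked, ranked_from_order
from oracles import naive_kendall_distance, naive_signed_ks
from phenonet.signatures import (
    EntityClass,
    GeneSetSignature,
    GeneUniverse,
    PhenotypicEntity,
)
from phenonet.similarity import (
    compute_similarity_matrix,
    directional_ks_similarity,
    jaccard,
    kendall_tau_normalized,
    kendall_tau_raw,
    metric_for_pair,
    signed_jaccard,
    signed_ks_statistic,
)


def geneset(up, down=(), eid="gs"):
    return GeneSetSignature(
        PhenotypicEntity(eid, EntityClass.DISEASE), frozenset(up), frozenset(down)
    )


class TestJaccard:
    def test_identical_sets_give_one(self):
        assert jaccard({"g1", "g2", "g3"}, {"g1", "g2", "g3"}) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert jaccard({"a", "b"}, {"c", "d"}) == 0.0

    def test_partial_overlap(self):
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())

    @settings(deadline=None, max_examples=50)
    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_symmetric_and_bounded(self, a, b):
        a, b = {str(x) for x in a}, {str(x) for x in b}
        if not (a | b):
            return
        v = jaccard(a, b)
        assert v == jaccard(b, a)
        assert 0.0 <= v <= 1.0


class TestSignedJaccard:
    def test_identical_signature_gives_plus_one(self):
        s = geneset({"a", "b"}, {"c"})
        assert signed_jaccard(s, s) == 1.0

    def test_direction_swap_gives_minus_one(self):
        s = geneset({"a", "b"}, {"c"})
        assert signed_jaccard(s, s.swapped()) == -1.0

    def test_up_only_reduces_to_plain_jaccard(self):
        assert signed_jaccard(geneset({"a", "b"}), geneset({"b", "c"})) == pytest.approx(1 / 3)

    def test_mixed_agreement_counts_signed(self):
        # shared: b same direction, c opposite; union {a,b,c,d}
        s1 = geneset({"a", "b"}, {"c"})
        s2 = geneset({"b", "c"}, {"d"})
        assert signed_jaccard(s1, s2) == pytest.approx((1 - 1) / 4)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        uni = GeneUniverse([f"g{i}" for i in range(12)])
        s1, s2 = random_geneset(uni, rng), random_geneset(uni, rng)
        v = signed_jaccard(s1, s2)
        assert v == signed_jaccard(s2, s1)
        assert -1.0 <= v <= 1.0


class TestKendall:
    def test_identical_lists_distance_zero(self, universe10):
        t = random_ranked(universe10, np.random.default_rng(0))
        assert kendall_tau_raw(t, t) == 0
        assert kendall_tau_normalized(t, t) == 1.0

    def test_reversal_reaches_maximum(self):
        uni = GeneUniverse(["a", "b", "c", "d"])
        t = ranked_from_order(uni, ("a", "b", "c", "d"))
        assert kendall_tau_raw(t, t.reversed()) == 6  # all 6 pairs discordant
        assert kendall_tau_normalized(t, t.reversed()) == -1.0

    def test_single_adjacent_swap(self):
        uni = GeneUniverse(["a", "b", "c"])
        t1 = ranked_from_order(uni, ("a", "b", "c"))
        t2 = ranked_from_order(uni, ("a", "c", "b"))
        assert kendall_tau_raw(t1, t2) == 1
        assert kendall_tau_normalized(t1, t2) == pytest.approx(1 / 3)

    def test_mismatched_universes_rejected(self, universe10):
        other = GeneUniverse(["x", "y", "z"])
        t1 = random_ranked(universe10, np.random.default_rng(0))
        t2 = ranked_from_order(other, ("x", "y", "z"))
        with pytest.raises(ValueError, match="different gene universes"):
            kendall_tau_raw(t1, t2)

    def test_too_small_universe_rejected(self):
        uni = GeneUniverse(["only"])
        t = ranked_from_order(uni, ("only",))
        with pytest.raises(ValueError, match="size < 2"):
            kendall_tau_normalized(t, t)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 60))
    def test_matches_naive_pair_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        uni = GeneUniverse([f"g{i:03d}" for i in range(n)])
        t1, t2 = random_ranked(uni, rng), random_ranked(uni, rng)
        assert kendall_tau_raw(t1, t2) == naive_kendall_distance(t1.order, t2.order)

    def test_agrees_with_scipy_kendalltau(self):
        rng = np.random.default_rng(5)
        uni = GeneUniverse([f"g{i:03d}" for i in range(150)])
        t1, t2 = random_ranked(uni, rng), random_ranked(uni, rng)
        tau_scipy = stats.kendalltau(t1.positions(), t2.positions()).statistic
        assert kendall_tau_normalized(t1, t2) == pytest.approx(tau_scipy, abs=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_reversal_is_minus_one_for_any_permutation(self, seed):
        rng = np.random.default_rng(seed)
        uni = GeneUniverse([f"g{i}" for i in range(15)])
        t = random_ranked(uni, rng)
        assert kendall_tau_normalized(t, t.reversed()) == -1.0


class TestSignedKs:
    def test_top_concentrated_set_is_positive(self, universe10):
        t = ranked_from_order(universe10, universe10.genes)
        assert signed_ks_statistic(t, set(t.order[:3])) > 0

    def test_bottom_concentrated_set_is_negative(self, universe10):
        t = ranked_from_order(universe10, universe10.genes)
        assert signed_ks_statistic(t, set(t.order[-3:])) < 0

    def test_single_top_gene_small_universe(self):
        uni = GeneUniverse(["a", "b", "c", "d"])
        t = ranked_from_order(uni, ("a", "b", "c", "d"))
        assert signed_ks_statistic(t, {"a"}) == pytest.approx(0.75)  # F_n(1)=1 vs F(1)=0.25

    def test_full_universe_is_background(self, universe10):
        t = random_ranked(universe10, np.random.default_rng(1))
        assert signed_ks_statistic(t, set(universe10.genes)) == pytest.approx(0.0, abs=1e-12)

    def test_empty_or_foreign_set_rejected(self, universe10):
        t = random_ranked(universe10, np.random.default_rng(2))
        with pytest.raises(ValueError, match="empty"):
            signed_ks_statistic(t, set())
        with pytest.raises(ValueError, match="zzz"):
            signed_ks_statistic(t, {"zzz"})

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 30), st.integers(1, 10))
    def test_matches_step_enumeration_oracle(self, seed, n, k):
        rng = np.random.default_rng(seed)
        k = min(k, n)
        uni = GeneUniverse([f"g{i:02d}" for i in range(n)])
        t = random_ranked(uni, rng)
        members = set(np.array(t.order)[rng.permutation(n)[:k]])
        pos = sorted(np.sort(t.positions()[uni.indices(members)]))
        assert signed_ks_statistic(t, members) == pytest.approx(naive_signed_ks(pos, n))


class TestDirectionalKs:
    def test_concordant_positive_and_swap_antisymmetric(self, universe10):
        t = ranked_from_order(universe10, universe10.genes)
        sig = geneset(set(t.order[:2]), set(t.order[-2:]))
        v = directional_ks_similarity(t, sig)
        assert v > 0
        assert directional_ks_similarity(t, sig.swapped()) == pytest.approx(-v)

    def test_matches_per_direction_oracle(self):
        uni = GeneUniverse([f"g{i:02d}" for i in range(10)])
        t = ranked_from_order(uni, uni.genes)
        sig = geneset(set(t.order[:2]), set(t.order[-2:]))
        d_up = naive_signed_ks([1, 2], 10)
        d_down = naive_signed_ks([9, 10], 10)
        assert directional_ks_similarity(t, sig) == pytest.approx((d_up - d_down) / 2)

    def test_single_direction_used_unscaled(self, universe10):
        t = ranked_from_order(universe10, universe10.genes)
        up_only = geneset(set(t.order[:3]))
        assert directional_ks_similarity(t, up_only) == pytest.approx(
            signed_ks_statistic(t, set(t.order[:3]))
        )
        down_only = geneset(set(), set(t.order[:3]))
        assert directional_ks_similarity(t, down_only) == pytest.approx(
            -signed_ks_statistic(t, set(t.order[:3]))
        )


class TestSimilarityMatrix:
    def _collection(self, rng, n=12):
        uni = GeneUniverse([f"g{i:02d}" for i in range(20)])
        entities, sigs = [], {}
        for i in range(n):
            e = make_entity(i)
            entities.append(e)
            if e.is_ranked:
                sigs[e.id] = random_ranked(uni, rng, e)
            else:
                sigs[e.id] = random_geneset(uni, rng, e, n_up=4, n_down=4)
        return entities, sigs

    def test_metric_dispatch_counts_one_per_class(self):
        rng = np.random.default_rng(0)
        entities, sigs = self._collection(rng, n=4)  # one entity per class
        mat = compute_similarity_matrix(entities, sigs)
        iu, ju = np.triu_indices(4, k=1)
        metrics = sorted(str(m) for m in mat.metrics[iu, ju])
        assert metrics == ["jaccard", "kendall", "ks", "ks", "ks", "ks"]

    def test_duplicate_signature_gets_self_similarity(self, universe10):
        rng = np.random.default_rng(3)
        e1, e2 = make_entity(0, EntityClass.ENM), make_entity(1, EntityClass.ENM)
        t = random_ranked(universe10, rng, e1)
        t2 = ranked_from_order(universe10, t.order, e2)
        mat = compute_similarity_matrix([e1, e2], {e1.id: t, e2.id: t2})
        assert mat.value(e1.id, e2.id) == 1.0

    def test_cells_match_directly_invoked_metrics(self):
        rng = np.random.default_rng(11)
        entities, sigs = self._collection(rng, n=12)
        mat = compute_similarity_matrix(entities, sigs)
        assert np.allclose(mat.values, mat.values.T)
        assert np.all(np.abs(mat.values) <= 1.0 + 1e-12)
        for i, a in enumerate(entities):
            for j in range(i + 1, len(entities)):
                b = entities[j]
                sa, sb = sigs[a.id], sigs[b.id]
                metric = metric_for_pair(a, b)
                if metric == "kendall":
                    expected = kendall_tau_normalized(sa, sb)
                elif metric == "jaccard":
                    expected = signed_jaccard(sa, sb)
                elif a.is_ranked:
                    expected = directional_ks_similarity(sa, sb)
                else:
                    expected = directional_ks_similarity(sb, sa)
                assert mat.values[i, j] == pytest.approx(expected)
                assert mat.metric(a.id, b.id) == metric

    def test_entity_without_signature_rejected_by_id(self, universe10):
        e = make_entity(0, EntityClass.ENM)
        with pytest.raises(ValueError, match=e.id):
            compute_similarity_matrix([e], {})

    def test_wrong_signature_kind_rejected(self, universe10):
        e = make_entity(0, EntityClass.ENM)
        sig = random_geneset(universe10, np.random.default_rng(0), e)
        with pytest.raises(ValueError, match="RankedSignature"):
            compute_similarity_matrix([e], {e.id: sig})
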