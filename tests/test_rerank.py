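import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volcbir.retrieval import RankedList
from volcbir.rerank import (
    cmir_rank_score,
    cmir_rerank,
    rrf_rerank,
    rrf_scores,
    similarity_matrix,
)
from volcbir.synth import GeneratorConfig, generate_cohort, plant_copy

from conftest import random_unit_rows


def cmir_oracle(m_q, m_w):
    """Brute-force nested loop over all (i, j) slice pairs."""
    total = 0.0
    for i in range(m_q.shape[0]):
        best = -np.inf
        for j in range(m_w.shape[0]):
            best = max(best, float(np.dot(m_q[i], m_w[j])))
        total += best
    return total


class TestSimilarityMatrix:
    def test_identity_diagonal(self):
        m = np.eye(3)
        np.testing.assert_allclose(np.diag(similarity_matrix(m, m)), 1.0)

    def test_f1_by_hand(self, f1_cohort):
        sim_a = similarity_matrix(f1_cohort["Q"].matrix, f1_cohort["A"].matrix)
        np.testing.assert_allclose(sim_a, [[1.0, 0.6], [0.0, 0.8]], atol=1e-6)
        sim_b = similarity_matrix(f1_cohort["Q"].matrix, f1_cohort["B"].matrix)
        np.testing.assert_allclose(sim_b, [[0.6, 0.0], [0.8, 1.0]], atol=1e-6)

    def test_shape_error(self):
        with pytest.raises(ValueError):
            similarity_matrix(np.eye(2), np.eye(3))


class TestRankScore:
    def test_f1_values(self, f1_cohort):
        q = f1_cohort["Q"].matrix
        assert cmir_rank_score(similarity_matrix(q, f1_cohort["A"].matrix)) == pytest.approx(1.8, abs=1e-6)
        assert cmir_rank_score(similarity_matrix(q, f1_cohort["B"].matrix)) == pytest.approx(1.6, abs=1e-6)

    def test_all_ones_attains_upper_bound(self):
        assert cmir_rank_score(np.ones((7, 3))) == pytest.approx(7.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(1, 8), st.integers(1, 10), st.integers(2, 16), st.integers(0, 2**31 - 1))
    def test_matches_nested_loop_oracle(self, n, m, L, seed):
        rng = np.random.default_rng(seed)
        m_q = random_unit_rows(rng, n, L)
        m_w = random_unit_rows(rng, m, L)
        sim = similarity_matrix(m_q, m_w)
        assert cmir_rank_score(sim) == pytest.approx(cmir_oracle(m_q, m_w), abs=1e-9)

    def test_monotone_in_entries(self):
        rng = np.random.default_rng(1)
        sim = rng.uniform(-1, 1, size=(5, 6))
        base = cmir_rank_score(sim)
        for _ in range(20):
            i, j = rng.integers(5), rng.integers(6)
            bumped = sim.copy()
            bumped[i, j] += rng.uniform(0, 0.5)
            assert cmir_rank_score(bumped) >= base - 1e-12


class TestCmirRerank:
    def test_f1_order_any_incoming_order(self, f1_cohort):
        for incoming in (["B", "A"], ["A", "B"]):
            cand = RankedList(method="count", query_id="Q", items=[(v, 1.0) for v in incoming])
            out = cmir_rerank(f1_cohort["Q"], cand, f1_cohort)
            assert [v for v, _ in out.items] == ["A", "B"]
            assert out.items[0][1] == pytest.approx(1.8, abs=1e-6)
            assert out.items[1][1] == pytest.approx(1.6, abs=1e-6)
            assert out.method == "cmir"

    def test_membership_only_permuted(self, f1_cohort):
        cand = RankedList(method="count", query_id="Q", items=[("B", 2.0), ("A", 1.0)])
        out = cmir_rerank(f1_cohort["Q"], cand, f1_cohort)
        assert sorted(out.volume_ids) == ["A", "B"]

    def test_single_candidate_unchanged(self, f1_cohort):
        cand = RankedList(method="count", query_id="Q", items=[("B", 1.0)])
        assert cmir_rerank(f1_cohort["Q"], cand, f1_cohort).volume_ids == ["B"]

    def test_missing_candidate_raises(self, f1_cohort):
        cand = RankedList(method="count", query_id="Q", items=[("ZZ", 1.0)])
        with pytest.raises(KeyError):
            cmir_rerank(f1_cohort["Q"], cand, f1_cohort)

    def test_self_retrieval_supremacy(self):
        cohort = generate_cohort(
            GeneratorConfig(volumes_per_class=1, slice_count_range=(4, 8), seed=13)
        )
        vid = cohort.volume_ids[7]
        planted = plant_copy(cohort, vid)
        query = planted[vid]
        cand = RankedList(
            method="count",
            query_id=vid,
            items=[(v, 0.0) for v in planted.volume_ids if v != vid],
        )
        out = cmir_rerank(query, cand, planted, M=len(cand))
        assert out.items[0][0] == f"{vid}__copy"
        assert out.items[0][1] == pytest.approx(query.n_slices, abs=1e-6)
        # supremacy: no other candidate can reach rs = n
        assert all(s <= query.n_slices + 1e-9 for _, s in out.items)

    def test_ties_preserve_incoming_order(self, f1_cohort):
        # duplicate candidate matrices => equal rank scores
        from volcbir.datamodel import Cohort
        from conftest import make_volume

        a = make_volume("A", [(1.0, 0.0)])
        b = make_volume("B", [(1.0, 0.0)])
        q = make_volume("Q", [(0.6, 0.8)])
        cohort = Cohort(records=[q, a, b], embedding_dim=2)
        cand = RankedList(method="count", query_id="Q", items=[("B", 1.0), ("A", 0.5)])
        assert cmir_rerank(q, cand, cohort).volume_ids == ["B", "A"]


def _lists(*orders):
    return [
        RankedList(method=m, query_id="Q", items=[(v, float(len(o) - i)) for i, v in enumerate(o)])
        for m, o in zip(("count", "max_score", "sum_sim"), orders)
    ]


class TestRrf:
    def test_rank1_in_all_lists(self):
        lists = _lists(["V"], ["V"], ["V"])
        assert rrf_scores(lists)["V"] == pytest.approx(3 / 61)

    def test_partial_membership(self):
        lists = _lists(["A", "V"], ["A", "B", "V"], ["A"])
        assert rrf_scores(lists)["V"] == pytest.approx(1 / 62 + 1 / 63)

    def test_absent_everywhere_not_in_map(self):
        lists = _lists(["A"], ["A"], ["A"])
        assert "V" not in rrf_scores(lists)

    def test_wrong_list_count_rejected(self):
        lists = _lists(["A"], ["A"])
        with pytest.raises(ValueError):
            rrf_scores(lists)

    def test_identical_lists_preserve_order(self):
        lists = _lists(["A", "B", "C"], ["A", "B", "C"], ["A", "B", "C"])
        assert rrf_rerank(lists).volume_ids == ["A", "B", "C"]

    def test_majority_arithmetic(self):
        lists = _lists(["A", "B"], ["B", "A"], ["A", "B"])
        out = rrf_rerank(lists)
        assert out.volume_ids == ["A", "B"]
        assert out.items[0][1] == pytest.approx(2 / 61 + 1 / 62)

    def test_rank_only_invariance(self):
        rng = np.random.default_rng(4)
        orders = (["A", "B", "C"], ["C", "A"], ["B", "A", "D"])
        base = rrf_rerank(_lists(*orders))
        for _ in range(25):
            perturbed = [
                RankedList(
                    method=l.method,
                    query_id="Q",
                    items=[
                        (v, s * rng.uniform(0.5, 2.0) + i * 0.0)
                        for i, (v, s) in enumerate(
                            zip(l.volume_ids, sorted(rng.uniform(1, 9, len(l)), reverse=True))
                        )
                    ],
                )
                for l in _lists(*orders)
            ]
            out = rrf_rerank(perturbed)
            assert out.volume_ids == base.volume_ids
            assert [s for _, s in out.items] == [s for _, s in base.items]
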