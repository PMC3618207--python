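"""Similarities, assignment schemes, and the reconstruction harness."""

import itertools

import numpy as np
import pytest

from ldalr import (Criterion, ProtocolDocument, criterion_cosine,
                   document_cosine, lmt_assign, restrict_top_fraction,
                   rnd_assign, run_reconstruction, select_neighbors,
                   summarize, sweep_topics)
from ldalr.evaluation import (assign_greedy_injective, assign_per_target_max,
                              assign_random, evaluate_target,
                              similarity_matrix)


def _crit(text, kind="inclusion", src="d"):
    return Criterion(text, kind, src)


def _doc(doc_id, text):
    return ProtocolDocument(id=doc_id, pico={"P": text})


class TestCosine:
    def test_identity_and_orthogonality(self):
        a = _doc("a", "alpha beta gamma")
        b = _doc("b", "alpha beta gamma")
        c = _doc("c", "delta epsilon")
        assert document_cosine(a, b) == pytest.approx(1.0)
        assert document_cosine(a, c) == 0.0

    def test_half_overlap_hand_value(self):
        # tf vectors {a:1,b:1} vs {b:1,c:1} -> 1/(sqrt2*sqrt2) = 0.5
        s1 = _crit("alpha beta")
        s2 = _crit("beta gamma")
        assert criterion_cosine(s1, s2) == pytest.approx(0.5)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        words = ["w" + c for c in "abcdefgh"]
        for _ in range(20):
            s1 = _crit(" ".join(rng.choice(words, size=5)))
            s2 = _crit(" ".join(rng.choice(words, size=5)))
            assert criterion_cosine(s1, s2) == criterion_cosine(s2, s1)

    def test_empty_document_similarity_zero(self):
        assert document_cosine(_doc("a", ""), _doc("b", "alpha")) == 0.0


class TestNeighbors:
    def test_verbatim_copy_is_a_neighbor(self):
        target = _doc("t", "alpha beta gamma")
        copy = _doc("c", "alpha beta gamma")
        far = _doc("f", "delta epsilon zeta")
        assert [d.id for d in select_neighbors(target, [target, copy, far])] \
            == ["c"]

    def test_disjoint_corpus_has_no_neighbors(self):
        target = _doc("t", "alpha")
        corpus = [_doc("a", "beta"), _doc("b", "gamma")]
        assert select_neighbors(target, corpus) == []

    def test_zero_threshold_keeps_everything_but_self(self):
        target = _doc("t", "alpha")
        corpus = [target, _doc("a", "beta")]
        assert len(select_neighbors(target, corpus, threshold=0.0)) == 1


class TestPerTargetMax:
    def test_matches_exhaustive_search_on_2x3(self):
        M = np.array([[0.1, 0.9, 0.4], [0.8, 0.2, 0.3]])
        a = assign_per_target_max(M, "LMT")
        assert a.sims == [0.9, 0.8]
        assert a.mean == pytest.approx(0.85)
        # brute force over all 9 per-target choices
        best = max(np.mean([M[0, i], M[1, j]])
                   for i in range(3) for j in range(3))
        assert a.mean == pytest.approx(best)

    def test_single_target_single_candidate(self):
        a = assign_per_target_max(np.array([[0.3]]))
        assert a.mapping == [0] and a.is_solution

    def test_reuse_allowed_flags_non_solution(self):
        M = np.array([[0.9, 0.1], [0.8, 0.1]])
        a = assign_per_target_max(M, "ITR")
        assert a.mapping == [0, 0]
        assert not a.is_solution

    def test_full_pool_containing_targets_gives_mean_one(self):
        targets = [_crit("alpha beta"), _crit("gamma delta")]
        pool = [_crit("unrelated zeta")] + targets
        a = lmt_assign(targets, pool)
        assert a.mean == pytest.approx(1.0)

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            assign_per_target_max(np.empty((0, 3)))


class TestRandomAssignment:
    def test_expectation_equals_matrix_mean(self):
        M = np.array([[0.1, 0.9, 0.4], [0.8, 0.2, 0.3]])
        means = [assign_random(M, seed).mean for seed in range(4000)]
        assert np.mean(means) == pytest.approx(M.mean(), abs=0.01)

    def test_identical_candidates_make_seed_irrelevant(self):
        M = np.tile([[0.4], [0.7]], (1, 5))
        for seed in range(5):
            assert assign_random(M, seed).mean == pytest.approx(0.55)

    def test_seed_reproducible(self):
        M = np.random.default_rng(0).random((4, 7))
        assert assign_random(M, 9).mapping == assign_random(M, 9).mapping


class TestIterative:
    def test_dominates_every_injective_assignment(self):
        rng = np.random.default_rng(3)
        M = rng.random((3, 4))
        itr = assign_per_target_max(M, "ITR")
        for perm in itertools.permutations(range(4), 3):
            inj_mean = np.mean([M[i, perm[i]] for i in range(3)])
            assert itr.mean >= inj_mean - 1e-12

    def test_restricted_pool_containing_targets_gives_one(self):
        targets = [_crit("alpha"), _crit("beta")]
        a = assign_per_target_max(similarity_matrix(targets, targets), "ITR")
        assert a.mean == pytest.approx(1.0)


class TestGreedyInjective:
    def test_documented_2x2_suboptimality(self):
        # greedy commits (t1,c1)=0.9 then forces (t2,c2)=0.1 -> mean 0.5,
        # while the optimal injective assignment reaches 0.825
        M = np.array([[0.9, 0.8], [0.85, 0.1]])
        a = assign_greedy_injective(M)
        assert a.mapping == [0, 1]
        assert a.mean == pytest.approx(0.5)
        opt = max(np.mean([M[0, p[0]], M[1, p[1]]])
                  for p in itertools.permutations(range(2)))
        assert opt == pytest.approx(0.825)
        assert a.mean < opt

    def test_always_injective_solution(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            M = rng.random((4, 6))
            a = assign_greedy_injective(M)
            assert a.is_solution
            assert len(set(a.mapping)) == 4

    def test_pool_exhaustion_recycles_candidates(self, caplog):
        M = np.array([[0.5], [0.4], [0.3]])
        with caplog.at_level("WARNING"):
            a = assign_greedy_injective(M)
        assert a.mapping == [0, 0, 0]
        assert not a.is_solution

    def test_never_beats_per_target_max(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            M = rng.random((rng.integers(1, 6), rng.integers(1, 8)))
            assert assign_greedy_injective(M).mean <= \
                assign_per_target_max(M).mean + 1e-12


class TestRestrictTopFraction:
    class _FakeRanked:
        def __init__(self, n):
            from ldalr.scoring import RankedCriteria, ScoredCriterion
            items = [ScoredCriterion(_crit(f"c{i}"), 1.0 - i / n, i)
                     for i in range(n)]
            self.ranked = RankedCriteria(kind="inclusion", items=items)

    @pytest.mark.parametrize("n,frac,expect", [
        (10, 0.30, 3), (10, 1.0, 10), (1, 0.30, 1), (7, 0.30, 3)])
    def test_ceiling_rounding(self, n, frac, expect):
        ranked = self._FakeRanked(n).ranked
        assert len(restrict_top_fraction(ranked, frac)) == expect

    def test_empty_ranking_rejected(self):
        from ldalr.scoring import RankedCriteria
        with pytest.raises(ValueError):
            restrict_top_fraction(RankedCriteria("inclusion", []), 0.3)


class TestSummarize:
    def test_normalization_identities(self):
        rows = summarize({"LMT": 0.5, "ITR": 0.4, "BFS": 0.35, "RND": 0.05})
        assert rows["LMT"]["normalized"] == pytest.approx(100.0)
        assert rows["RND"]["pct_vs_random"] == pytest.approx(100.0)
        assert rows["ITR"]["normalized"] == pytest.approx(80.0)
        assert rows["ITR"]["pct_vs_random"] == pytest.approx(800.0)

    def test_all_equal_averages_collapse_to_100(self):
        rows = summarize({m: 1.0 for m in ("LMT", "ITR", "BFS", "RND")})
        for m in rows:
            assert rows[m]["normalized"] == pytest.approx(100.0)


class TestReconstruction:
    def test_ordering_chain_holds_per_observation_point(self,
                                                        default_pipeline):
        """LMT >= ITR >= BFS and LMT >= RND on every observation point."""
        _, records = run_reconstruction(
            default_pipeline["test"][:12], default_pipeline["train"],
            default_pipeline["model"], default_pipeline["csets"], seed=0)
        assert records
        for r in records:
            assert r.means["LMT"] >= r.means["ITR"] - 1e-12
            assert r.means["ITR"] >= r.means["BFS"] - 1e-12
            assert r.means["LMT"] >= r.means["RND"] - 1e-12

    def test_pool_accounting_matches_neighbor_criteria(self,
                                                       default_pipeline):
        train = default_pipeline["train"]
        by_id = {d.id: d for d in train}
        for d_tau in default_pipeline["test"][:6]:
            rec = evaluate_target(d_tau, "exclusion", train,
                                  default_pipeline["model"],
                                  default_pipeline["csets"]["exclusion"])
            if rec is None:
                continue
            nbrs = select_neighbors(d_tau, train)
            expected = sum(len(by_id[d.id].exclusion) for d in nbrs)
            assert rec.n_candidates == expected
            assert rec.n_neighbors == len(nbrs)
            assert rec.n_targets == len(d_tau.exclusion)

    def test_summary_normalization_by_construction(self, default_pipeline):
        summaries, _ = run_reconstruction(
            default_pipeline["test"][:12], default_pipeline["train"],
            default_pipeline["model"], default_pipeline["csets"], seed=0)
        for s in summaries.values():
            assert s.normalized["LMT"] == pytest.approx(100.0)
            assert s.pct_vs_random["RND"] == pytest.approx(100.0)
            for m in ("ITR", "BFS", "RND"):
                assert s.normalized[m] == pytest.approx(
                    100.0 * s.avg_sim[m] / s.avg_sim["LMT"])

    def test_restricted_methods_beat_random_on_average(self,
                                                       default_pipeline):
        """Averaged over many observation points, the ranked-and-restricted
        schemes strictly exceed the random baseline (the empirical
        lower-bound property of expected-value scoring)."""
        summaries, records = run_reconstruction(
            default_pipeline["test"], default_pipeline["train"],
            default_pipeline["model"], default_pipeline["csets"], seed=0)
        assert len(records) >= 50
        for s in summaries.values():
            assert s.avg_sim["ITR"] > s.avg_sim["RND"]
            assert s.avg_sim["BFS"] > s.avg_sim["RND"]
            assert s.avg_sim["ITR"] <= s.avg_sim["LMT"]

    def test_determinism_of_reports(self, default_pipeline):
        kw = dict(targets=default_pipeline["test"][:8],
                  corpus=default_pipeline["train"],
                  model=default_pipeline["model"],
                  classifier_sets=default_pipeline["csets"], seed=5)
        s1, _ = run_reconstruction(**kw)
        s2, _ = run_reconstruction(**kw)
        assert {k: v.to_dict() for k, v in s1.items()} == \
            {k: v.to_dict() for k, v in s2.items()}


class TestSweep:
    def test_series_shape_and_determinism(self, small_corpus):
        docs = small_corpus.documents
        kw = dict(n_values=[2, 3], train_docs=docs[10:60],
                  target_docs=docs[:6], kinds=("exclusion",), seed=0,
                  iterations=10)
        s1 = sweep_topics(**kw)
        s2 = sweep_topics(**kw)
        assert [e["n"] for e in s1] == [2, 3]
        assert s1 == s2

    def test_single_value_sweep_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            sweep_topics([5], small_corpus.documents, [])
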