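import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herbscreen.synthetic import GeneratorConfig, generate_refsets, make_query
from herbscreen.targets import (
    ConsensusTargets,
    ReferenceSet,
    TargetPrediction,
    consensus_targets,
    enrich,
    predict_bayes,
    predict_cats_nn,
    predict_nn,
    predict_sea_like,
)


@pytest.fixture(scope="module")
def refsets():
    sets, _ = generate_refsets(GeneratorConfig(n_targets=4, n_ligands_per_target=12,
                                               seed=21))
    return sets


class TestPredictNN:
    def test_identical_ligand_scores_one(self, refsets):
        query = refsets[0].ligands[0]
        pred = predict_nn(query, refsets, cutoff=1.0)
        assert pred.scores[refsets[0].target_id] == pytest.approx(1.0)
        assert refsets[0].target_id in pred.predicted

    def test_dissimilar_query_predicts_nothing(self, refsets):
        pred = predict_nn("C", refsets, cutoff=0.5)
        assert pred.predicted == set()

    def test_refset_order_invariance(self, refsets):
        a = predict_nn("CCO", refsets).scores
        b = predict_nn("CCO", list(reversed(refsets))).scores
        assert a == b


class TestPredictSeaLike:
    def test_dissimilar_query_not_predicted(self, refsets):
        pred = predict_sea_like("C", refsets, n_null=100, seed=0)
        assert all(z <= 0 for z in pred.scores.values())
        assert pred.predicted == set()

    def test_deterministic_per_seed(self, refsets):
        q = refsets[1].ligands[0]
        a = predict_sea_like(q, refsets, n_null=100, seed=7).scores
        b = predict_sea_like(q, refsets, n_null=100, seed=7).scores
        assert a == b

    def test_n_null_floor(self, refsets):
        with pytest.raises(ValueError):
            predict_sea_like("C", refsets, n_null=10, seed=0)


class TestPredictBayes:
    def test_matching_ligands_outrank_disjoint_target(self):
        sets = [ReferenceSet("T1", ["CCO", "CCO"]),
                ReferenceSet("T2", ["c1ccccc1", "c1ccccc1"])]
        pred = predict_bayes("CCO", sets)
        assert pred.scores["T1"] > pred.scores["T2"]

    def test_duplicated_refsets_score_identically(self):
        sets = [ReferenceSet("T1", ["CCO", "CCN"]), ReferenceSet("T2", ["CCO", "CCN"])]
        pred = predict_bayes("CCOC", sets)
        assert pred.scores["T1"] == pytest.approx(pred.scores["T2"])

    def test_undersized_refset_skipped(self):
        sets = [ReferenceSet("T1", ["CCO"]), ReferenceSet("T2", ["CCN", "CCO"])]
        pred = predict_bayes("CCO", sets)
        assert set(pred.scores) == {"T2"}


class TestPredictCatsNN:
    def test_identical_ligand_distance_zero(self, refsets):
        query = refsets[2].ligands[0]
        pred = predict_cats_nn(query, refsets)
        assert pred.scores[refsets[2].target_id] == pytest.approx(1.0)

    def test_score_decreases_with_distance(self):
        assert 1 / (1 + 0.5) > 1 / (1 + 2.0)  # the kernel itself
        sets = [ReferenceSet("T1", ["CCO", "CCN"])]
        s_near = predict_cats_nn("CCO", sets).scores["T1"]
        s_far = predict_cats_nn("NC(=O)CCCCN", sets).scores["T1"]
        assert s_near > s_far


@pytest.mark.parametrize("method,threshold", [
    (predict_nn, 0.90), ("sea", 0.80), (predict_bayes, 0.80), (predict_cats_nn, 0.80),
])
def test_planted_motif_recovery_rate(refsets, method, threshold):
    """Queries carrying a target's motif should rank that target first in
    the large majority of seeded trials, for every method."""
    config = GeneratorConfig(n_targets=4, n_ligands_per_target=12, seed=21)
    n_trials, hits = 40, 0
    for trial in range(n_trials):
        target_idx = trial % 4
        query = make_query(config, target_idx, seed=1000 + trial)
        if method == "sea":
            pred = predict_sea_like(query, refsets, n_null=150, seed=trial)
        else:
            pred = method(query, refsets)
        hits += pred.argmax() == f"T{target_idx + 1}"
    assert hits / n_trials >= threshold


class TestConsensusTargets:
    def test_vote_logic(self):
        preds = [TargetPrediction(m, {"T1": 1.0, "T2": 1.0},
                                  {"T1"} if i < 3 else {"T2"})
                 for i, m in enumerate("abcd")]
        preds[0].predicted.add("T2")
        preds[1].predicted.add("T2")
        cons = consensus_targets(preds, min_methods=3)
        assert cons.votes == {"T1": 3, "T2": 3}
        assert cons.consensus == {"T1", "T2"}

    def test_all_methods_agree(self):
        preds = [TargetPrediction(m, {"T5": 0.9}, {"T5"}) for m in "abcd"]
        assert consensus_targets(preds).votes["T5"] == 4

    def test_min_methods_exceeding_supply(self):
        preds = [TargetPrediction("a", {"T1": 1.0}, {"T1"})]
        with pytest.raises(ValueError):
            consensus_targets(preds, min_methods=3)

    @given(st.lists(st.sets(st.sampled_from(["T1", "T2", "T3", "T4", "T5"])),
                    min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_anti_monotone_in_min_methods(self, predicted_sets):
        preds = [TargetPrediction(f"m{i}", {t: 1.0 for t in s} or {"T0": 0.0}, set(s))
                 for i, s in enumerate(predicted_sets)]
        sets = [consensus_targets(preds, m).consensus for m in (1, 2, 3, 4)]
        for smaller, larger in zip(sets[1:], sets):
            assert smaller <= larger

    def test_ranked_orders_by_mean_score(self):
        preds = [TargetPrediction(m, {"T1": hi, "T2": lo}, {"T1", "T2"})
                 for m, (hi, lo) in zip("abcd", [(0.9, 0.4)] * 4)]
        ranked = consensus_targets(preds, min_methods=3).ranked()
        assert [t for t, _ in ranked] == ["T1", "T2"]


def brute_force_hypergeom_p(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all n-subsets of the universe."""
    universe = range(N)
    annotated = set(range(K))
    total = hits = 0
    for subset in combinations(universe, n):
        total += 1
        if len(annotated & set(subset)) >= k:
            hits += 1
    return hits / total


class TestEnrich:
    def test_worked_example_1_over_15504(self):
        universe = {f"t{i}" for i in range(20)}
        pathway = {f"t{i}" for i in range(5)}
        rows = enrich(pathway, {"P1": pathway}, universe)
        assert rows[0].p_value == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap_p_is_one(self):
        universe = {f"t{i}" for i in range(10)}
        rows = enrich({"t0", "t1"}, {"P1": {"t8", "t9"}}, universe)
        row = rows[0]
        assert row.k == 0 or row.p_value <= 1.0
        rows2 = enrich({"t8", "t9"}, {"P1": {"t0", "t1"}}, universe)
        assert rows2[0].p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universes(self):
        for N in (6, 9, 12):
            universe = {f"t{i}" for i in range(N)}
            for K in (2, N // 2):
                annotation = {"P": {f"t{i}" for i in range(K)}}
                for n in (2, min(5, N - 1)):
                    selected = {f"t{i}" for i in range(N - n, N)}
                    (row,) = enrich(selected, annotation, universe)
                    expected = brute_force_hypergeom_p(N, K, n, row.k)
                    assert row.p_value == pytest.approx(expected, rel=1e-9)

    def test_bh_step_up_by_hand(self):
        # p-values 0.01, 0.02, 0.03 over 3 pathways all adjust to 0.03
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])
        # and enrich applies the same correction across its rows
        universe = {f"t{i}" for i in range(12)}
        annotation = {"P1": {"t0", "t1", "t2"}, "P2": {"t3", "t4"},
                      "P3": {"t0", "t5", "t6", "t7"}}
        rows = enrich({"t0", "t1", "t3"}, annotation, universe)
        assert all(r.p_adjusted >= r.p_value for r in rows)
        assert [r.p_value for r in rows] == sorted(r.p_value for r in rows)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich(set(), {}, set())
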