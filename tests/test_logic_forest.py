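"""Forest fitting, OOB machinery, importance measures and discrimination."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from logicforest.logic_forest import (
    LogicForestModel,
    aggregate,
    fit_forest,
    oob_misclassification,
    oob_predict,
    oob_vote_shares,
    predict,
    roc_auc,
    tree_oob_misclassification,
    vi_frequency,
    vi_permutation,
)
from logicforest.logic_tree import AnnealingSchedule, Literal, LogicTree, PrimeImplicant

from conftest import make_dataset


def manual_forest(tree_texts, boots, n):
    trees = [LogicTree.from_text(t) for t in tree_texts]
    boots = [np.asarray(b) for b in boots]
    oobs = []
    for b in boots:
        inbag = np.zeros(n, dtype=bool)
        inbag[b] = True
        oobs.append(np.flatnonzero(~inbag))
    return LogicForestModel(trees, boots, oobs)


def naive_oob_recount(model, W):
    """Independent double-loop recount of Eq-1 predictions and Eq-2 error."""
    n = W.n
    preds = np.full(n, -1, dtype=int)
    for i in range(n):
        votes = []
        for b in range(model.B):
            if i in set(model.oob_indices[b].tolist()):
                votes.append(int(model.trees[b].evaluate(W.X[i:i + 1])[0]))
        if votes:
            preds[i] = 1 if sum(votes) / len(votes) >= 0.5 else 0
    voted = preds >= 0
    mc = float(np.mean([(int(W.y[i]) - preds[i]) ** 2 for i in range(n) if voted[i]]))
    return preds, mc


class TestBootstrap:
    def test_single_tree_oob_is_complement(self, planted_and_dataset):
        model = fit_forest(planted_and_dataset, B=1,
                           schedule=AnnealingSchedule.fast(100), rng=0)
        drawn = set(model.bootstrap_indices[0].tolist())
        oob = set(model.oob_indices[0].tolist())
        assert drawn | oob == set(range(planted_and_dataset.n))
        assert drawn & oob == set()

    def test_oob_fraction_near_1_over_e(self, planted_and_dataset):
        model = fit_forest(planted_and_dataset, B=20,
                           schedule=AnnealingSchedule.fast(100), rng=1)
        fracs = [o.size / planted_and_dataset.n for o in model.oob_indices]
        assert all(0.25 < f < 0.50 for f in fracs)

    def test_fixed_seed_reproducible(self, planted_and_dataset):
        kw = dict(B=5, schedule=AnnealingSchedule.fast(300))
        m1 = fit_forest(planted_and_dataset, rng=42, **kw)
        m2 = fit_forest(planted_and_dataset, rng=42, **kw)
        assert [t.to_text() for t in m1.trees] == [t.to_text() for t in m2.trees]
        for a, b in zip(m1.bootstrap_indices, m2.bootstrap_indices):
            np.testing.assert_array_equal(a, b)


class TestOOBPrediction:
    def test_majority_and_tie_rule(self):
        # subject 3 OOB in trees voting (1, 1, 0) -> 1; subject 4 votes (1, 0) -> tie -> 1
        X = np.array([[0]] * 3 + [[1], [1]], dtype=np.uint8)
        W = make_dataset(X, [0, 0, 0, 1, 0], names=["x0"])
        model = manual_forest(
            ["x0", "x0", "!x0", "!x0"],
            [[0, 1, 2], [0, 1, 2, 4], [0, 1, 2, 4], [0, 1, 2, 3]],
            n=5,
        )
        pred = oob_predict(model, W)
        assert pred[3] == 1  # votes (1, 1, 0) from trees 0-2
        assert pred[4] == 1  # votes (1, 0) from trees 0 and 3 -> share 0.5 -> >= rule
        assert pred[0] == -1 and pred[1] == -1  # in every bag: never OOB

    def test_all_zero_votes(self):
        X = np.array([[0], [0], [1]], dtype=np.uint8)
        W = make_dataset(X, [0, 1, 1], names=["x0"])
        model = manual_forest(["x0", "x0"], [[2, 2, 2], [0, 2, 2]], n=3)
        pred = oob_predict(model, W)
        assert pred[0] == 0 and pred[1] == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_eq2_matches_naive_recount(self, seed, rng):
        n = 20 + seed
        X = np.random.default_rng(seed).integers(0, 2, size=(n, 5)).astype(np.uint8)
        y = np.random.default_rng(seed + 100).integers(0, 2, n).astype(np.uint8)
        W = make_dataset(X, y)
        model = fit_forest(W, B=6, schedule=AnnealingSchedule.fast(60), rng=seed)
        preds, mc = naive_oob_recount(model, W)
        np.testing.assert_array_equal(oob_predict(model, W), preds)
        assert oob_misclassification(model, W) == pytest.approx(mc)

    def test_perfect_and_inverted_predictions(self):
        X = np.array([[0], [1], [0], [1]], dtype=np.uint8)
        model = manual_forest(["x0"], [[0, 1]], n=4)
        W_match = make_dataset(X, [1, 1, 0, 1], names=["x0"])  # oob rows 2,3: y=(0,1)=x0
        assert oob_misclassification(model, W_match) == 0.0
        W_flip = make_dataset(X, [1, 1, 1, 0], names=["x0"])
        assert oob_misclassification(model, W_flip) == 1.0


class TestTreeOOB:
    def test_constant_zero_tree_scores_oob_prevalence(self):
        X = np.zeros((10, 2), dtype=np.uint8)
        y = [1, 1, 0, 0, 0] + [1] * 5
        W = make_dataset(X, y)
        model = manual_forest(["x0"], [[5, 6, 7, 8, 9]], n=10)  # oob = first five
        assert tree_oob_misclassification(model, 0, W) == pytest.approx(0.4)

    def test_matches_recount(self, rng):
        X = rng.integers(0, 2, size=(15, 4)).astype(np.uint8)
        y = rng.integers(0, 2, 15).astype(np.uint8)
        W = make_dataset(X, y)
        model = fit_forest(W, B=3, schedule=AnnealingSchedule.fast(60), rng=5)
        for b in range(3):
            oob = model.oob_indices[b]
            yhat = model.trees[b].evaluate(X[oob])
            brute = np.mean(yhat != y[oob])
            assert tree_oob_misclassification(model, b, W) == pytest.approx(brute)


class TestImportance:
    def test_frequency_88_of_200(self):
        texts = ["x0"] * 88 + ["x1"] * 112
        model = manual_forest(texts, [[0, 1]] * 200, n=4)
        assert vi_frequency(model, PrimeImplicant((Literal(0, False),))) == 0.44
        assert vi_frequency(model, PrimeImplicant((Literal(2, False),))) == 0.0
        assert vi_frequency(model, PrimeImplicant((Literal(1, False),))) == 0.56

    def test_vi1_unused_predictor_exactly_zero(self, planted_and_dataset):
        model = fit_forest(planted_and_dataset, B=8,
                           schedule=AnnealingSchedule.fast(300), rng=3)
        unused = PrimeImplicant((Literal(7, False),))
        if not any(7 in t.predictor_indices for t in model.trees):
            assert vi_permutation(model, planted_and_dataset, unused, rng=0) == 0.0
            assert vi_permutation(model, planted_and_dataset, unused, rng=0,
                                  mode="columns") == 0.0

    def test_vi1_single_tree_arithmetic(self):
        # B=1: vi1 = MC_after - MC_before by definition
        X = np.array([[1], [1], [0], [0], [1], [0]], dtype=np.uint8)
        W = make_dataset(X, [1, 1, 0, 0, 1, 0], names=["x0"])
        model = manual_forest(["x0"], [[0, 1]], n=6)
        rng = np.random.default_rng(0)
        vi1 = vi_permutation(model, W, PrimeImplicant((Literal(0, False),)), rng=rng)
        # before permutation the tree is perfect on OOB (error 0); any
        # permutation cannot reduce error, so vi1 >= 0; bounded by 1
        assert 0.0 <= vi1 <= 1.0

    def test_vi1_bounds_and_vi2_identity(self, planted_and_dataset):
        model = fit_forest(planted_and_dataset, B=10,
                           schedule=AnnealingSchedule.fast(400), rng=4)
        counts = model.unique_prime_implicants()
        for pi, count in counts.items():
            assert vi_frequency(model, pi) == count / model.B
            v = vi_permutation(model, planted_and_dataset, pi, rng=1)
            assert -1.0 <= v <= 1.0

    def test_planted_pi_has_top_vi2(self, planted_and_dataset):
        model = fit_forest(planted_and_dataset, B=30,
                           schedule=AnnealingSchedule(n_iter=2000), rng=6)
        counts = model.unique_prime_implicants()
        planted = PrimeImplicant((Literal(1, False), Literal(2, False)))
        assert counts.get(planted, 0) == max(counts.values())

    def test_null_mean_vi1_near_zero(self, rng):
        X = rng.integers(0, 2, size=(300, 10)).astype(np.uint8)
        y = rng.permutation(np.r_[np.ones(150), np.zeros(150)]).astype(np.uint8)
        W = make_dataset(X, y)
        model = fit_forest(W, B=100, schedule=AnnealingSchedule.fast(400), rng=7)
        records, _ = aggregate(model, W, rng=8)
        mean_vi1 = float(np.mean([r.vi1 for r in records]))
        assert abs(mean_vi1) < 0.01


class TestAggregate:
    def test_identical_single_leaf_trees(self):
        X = np.array([[0], [1], [0], [1]], dtype=np.uint8)
        W = make_dataset(X, [0, 1, 0, 1], names=["x0"])
        model = manual_forest(["x0", "x0"], [[0, 1], [1, 2]], n=4)
        records, pred_records = aggregate(model, W, rng=0)
        assert len(records) == 1
        assert records[0].vi2 == 1.0 and records[0].tree_count == 2

    def test_normalisation_fixed_point(self, planted_and_dataset):
        model = fit_forest(planted_and_dataset, B=10,
                           schedule=AnnealingSchedule.fast(400), rng=9)
        records, _ = aggregate(model, planted_and_dataset, rng=10)
        best = max(records, key=lambda r: abs(r.vi1))
        if best.vi1 != 0:
            assert max(abs(r.normalized_vi1) for r in records) == pytest.approx(1.0)
            assert best.normalized_vi1 == pytest.approx(np.sign(best.vi1) * 1.0)

    def test_tree_counts_cover_forest(self, planted_and_dataset):
        model = fit_forest(planted_and_dataset, B=10,
                           schedule=AnnealingSchedule.fast(400), rng=11)
        records, _ = aggregate(model, planted_and_dataset, rng=12)
        if all(len(dnf) > 0 for dnf in model.tree_dnfs()):
            assert sum(r.tree_count for r in records) >= model.B


class TestPredict:
    def test_unanimous_and_tie(self):
        X = np.array([[1], [0]], dtype=np.uint8)
        model = manual_forest(["x0", "x0", "x0", "x0"], [[0]] * 4, n=2)
        share, label = predict(model, X)
        assert share.tolist() == [1.0, 0.0] and label.tolist() == [1, 0]
        model2 = manual_forest(["x0", "x0", "!x0", "!x0"], [[0]] * 4, n=2)
        share2, label2 = predict(model2, X)
        assert share2.tolist() == [0.5, 0.5] and label2.tolist() == [1, 1]

    def test_single_tree_reduces_to_evaluate(self, rng):
        X = rng.integers(0, 2, size=(20, 3)).astype(np.uint8)
        model = manual_forest(["(x0 AND !x2)"], [[0]], n=20)
        _, label = predict(model, X)
        np.testing.assert_array_equal(label, model.trees[0].evaluate(X))

    def test_missing_column_named(self):
        import pandas as pd

        model = manual_forest(["x0"], [[0]], n=2)
        with pytest.raises(KeyError, match="x0"):
            predict(model, pd.DataFrame({"other": [1, 0]}), names=["x0"])


class TestROC:
    def test_perfect_and_constant(self):
        y = np.array([0, 0, 1, 1])
        *_, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert auc == 1.0
        *_, auc0 = roc_auc(np.array([0.5, 0.5, 0.5, 0.5]), y)
        assert auc0 == 0.5

    def test_matches_mann_whitney(self):
        scores = np.array([0.1, 0.4, 0.4, 0.6, 0.7, 0.2])
        y = np.array([0, 1, 0, 1, 1, 0])
        *_, auc = roc_auc(scores, y)
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert auc == pytest.approx(u / (3 * 3))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestPersistence:
    def test_reload_reproduces_oob_quantities(self, tmp_path, planted_and_dataset):
        W = planted_and_dataset
        model = fit_forest(W, B=6, schedule=AnnealingSchedule.fast(300), rng=13)
        path = tmp_path / "model.json"
        model.save(path)
        back = LogicForestModel.load(path, W.n)
        assert oob_misclassification(back, W) == oob_misclassification(model, W)
        np.testing.assert_array_equal(oob_predict(back, W), oob_predict(model, W))
        shares_a, shares_b = oob_vote_shares(model, W), oob_vote_shares(back, W)
        np.testing.assert_allclose(shares_a, shares_b)
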