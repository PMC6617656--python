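import numpy as np
import pytest

import vacoder as vc

from conftest import make_toy_matrix


def separable_toy(n_per_class=20):
    """Two categories with disjoint single-stem vocabularies."""
    docs = [["cough", "cough"]] * n_per_class + [["fever", "fever"]] * n_per_class
    labels = ["resp"] * n_per_class + ["infection"] * n_per_class
    matrix, vocab, _ = make_toy_matrix(docs, ["adult"] * len(docs))
    return matrix, labels


@pytest.mark.parametrize("family", vc.FAMILIES)
def test_separable_toy_reaches_perfect_training_accuracy(family):
    matrix, labels = separable_toy()
    config = vc.ModelConfig(family=family, n_features=3, seed=0)
    model = vc.train(config, matrix, labels)
    assert model.predict(matrix) == labels


def test_naive_bayes_posterior_matches_hand_computation():
    # 100 docs per class over two complementary one-token features;
    # class A emits feature 0 ninety times in a hundred, class B ten.
    docs = (
        [["x"]] * 90 + [["y"]] * 10 + [["x"]] * 10 + [["y"]] * 90
    )
    labels = ["A"] * 100 + ["B"] * 100
    matrix, vocab, _ = make_toy_matrix(docs, ["adult"] * 200)
    model = vc.train(vc.ModelConfig("naive_bayes", n_features=3, seed=0), matrix, labels)
    probe = vc.build_feature_matrix(
        [vc.TokenizedNarrative("p", ["x"])], vocab, ["adult"]
    )
    ranked = model.predict_with_confidence(probe)[0]
    conf = dict(ranked)
    # hand-computed with add-one smoothing: theta_A,x = (90+1)/(100+2); the
    # equal-prior, equal-size age factor cancels, leaving 91/(91+11)
    assert conf["A"] == pytest.approx(91 / 102, abs=1e-9)
    assert abs(conf["A"] - 0.9) < 0.02  # within smoothing tolerance of 0.9


def test_high_confidence_on_separable_record():
    matrix, labels = separable_toy()
    model = vc.train(vc.ModelConfig("naive_bayes", n_features=3, seed=0), matrix, labels)
    ranked = model.predict_with_confidence(matrix)
    assert ranked[0][0][0] == "resp" and ranked[0][0][1] > 0.99


def test_uninformative_features_give_uniform_confidence():
    # identical rows, three equally sized classes: posterior must be 1/3
    docs = [["z"]] * 30
    labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
    matrix, _, _ = make_toy_matrix(docs, ["adult"] * 30)
    model = vc.train(vc.ModelConfig("naive_bayes", n_features=2, seed=0), matrix, labels)
    proba = model.confidence_matrix(matrix)
    np.testing.assert_allclose(proba, 1 / 3, atol=1e-9)


@pytest.mark.parametrize("family", vc.FAMILIES)
def test_confidences_normalized_and_ranked(family):
    matrix, labels = separable_toy(10)
    model = vc.train(vc.ModelConfig(family, n_features=3, seed=1), matrix, labels)
    ranked = model.predict_with_confidence(matrix)
    for row in ranked:
        confs = [c for _, c in row]
        assert sum(confs) == pytest.approx(1.0, abs=1e-9)
        assert confs == sorted(confs, reverse=True)
        assert all(c >= 0 for c in confs)
    assert model.predict(matrix) == [r[0][0] for r in ranked]


@pytest.mark.parametrize("family", ["random_forest", "ffnn"])
def test_retraining_with_same_seed_is_deterministic(family):
    matrix, labels = separable_toy()
    config = vc.ModelConfig(family, n_features=3, seed=7)
    a = vc.train(config, matrix, labels)
    b = vc.train(config, matrix, labels)
    np.testing.assert_array_equal(a.confidence_matrix(matrix), b.confidence_matrix(matrix))


@pytest.mark.parametrize("family", vc.FAMILIES)
def test_serialization_round_trip(tmp_path, family):
    matrix, labels = separable_toy(10)
    model = vc.train(vc.ModelConfig(family, n_features=3, seed=2), matrix, labels)
    model.save(tmp_path / family)
    loaded = vc.TrainedClassifier.load(tmp_path / family)
    assert loaded.predict(matrix) == model.predict(matrix)
    assert loaded.selected_names == model.selected_names


def test_training_errors():
    matrix, labels = separable_toy(5)
    with pytest.raises(ValueError, match="2 categories"):
        vc.train(vc.ModelConfig("naive_bayes"), matrix, ["same"] * len(labels))


def test_prediction_with_missing_columns_names_stems():
    matrix, labels = separable_toy(5)
    model = vc.train(vc.ModelConfig("naive_bayes", n_features=3, seed=0), matrix, labels)
    other, _, _ = make_toy_matrix([["unrelated"]], ["adult"])
    with pytest.raises(ValueError, match="cough|fever"):
        model.predict(other)


def test_shuffled_labels_stay_near_majority_baseline():
    # feature selection inside train() must not leak label information
    rng = np.random.default_rng(4)
    vocab_pool = [f"w{i}" for i in range(30)]
    docs = [list(rng.choice(vocab_pool, size=8)) for _ in range(300)]
    labels = list(rng.choice(["A", "B"], p=[0.7, 0.3], size=300))
    matrix, vocab, dlist = make_toy_matrix(docs, ["adult"] * 300)
    train_idx, test_idx = np.arange(200), np.arange(200, 300)
    sub_train, _, _ = make_toy_matrix([docs[i] for i in train_idx], ["adult"] * 200)
    model = vc.train(
        vc.ModelConfig("naive_bayes", n_features=20, seed=0),
        sub_train,
        [labels[i] for i in train_idx],
    )
    test_matrix, _, _ = make_toy_matrix([docs[i] for i in test_idx], ["adult"] * 100)
    preds = model.predict(test_matrix)
    y_test = [labels[i] for i in test_idx]
    acc = np.mean([p == t for p, t in zip(preds, y_test)])
    majority = max(np.mean([t == "A" for t in y_test]), np.mean([t == "B" for t in y_test]))
    assert acc <= majority + 0.1


class TestOptimize:
    def _data(self):
        matrix, labels = separable_toy(15)
        val_matrix, val_labels = separable_toy(5)
        return matrix, labels, val_matrix, val_labels

    def test_budget_one_returns_single_candidate(self):
        m, y, vm_, vy = self._data()
        spec = vc.SearchSpec("naive_bayes", budget=1, seed=3)
        best, trials = vc.optimize(spec, m, y, vm_, vy)
        assert len(trials) == 1
        assert best.n_features == trials[0]["n_features"]

    def test_same_seed_gives_identical_trial_sequence(self):
        m, y, vm_, vy = self._data()
        spec = vc.SearchSpec("random_forest", budget=5, seed=8)
        _, t1 = vc.optimize(spec, m, y, vm_, vy)
        _, t2 = vc.optimize(spec, m, y, vm_, vy)
        assert t1 == t2

    def test_search_approaches_exhaustive_grid_optimum(self):
        # oracle: exhaustively score a small candidate grid, then check the
        # random search comes within 5% of the best grid score
        m, y, vm_, vy = self._data()
        grid_scores = []
        for n_features in (2, 3):
            for alpha in (0.1, 1.0):
                model = vc.train(
                    vc.ModelConfig("naive_bayes", n_features, {"alpha": alpha}, seed=0),
                    m,
                    y,
                )
                preds = model.predict(vm_)
                table = vc.confusion_table(vy, preds, sorted(set(vy)))
                grid_scores.append(vc.prf(table)[1])
        best_grid = max(grid_scores)
        spec = vc.SearchSpec("naive_bayes", budget=20, seed=1)
        _, trials = vc.optimize(spec, m, y, vm_, vy)
        assert max(t["score"] for t in trials) >= 0.95 * best_grid
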