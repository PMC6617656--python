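import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vacoder as vc
from vacoder.metrics import per_category_prf


class TestPRF:
    def test_perfect_diagonal_under_every_averaging(self):
        table = vc.ConfusionTable(np.diag([5, 3, 2]), ("A", "B", "C"))
        for mode in ("weighted", "macro", "micro"):
            assert vc.prf(table, mode) == (1.0, 1.0, 1.0)

    def test_macro_sensitivity_worked_example(self):
        table = vc.ConfusionTable(np.array([[8, 2], [4, 6]]), ("A", "B"))
        _, sens, _ = vc.prf(table, "macro")
        assert sens == pytest.approx((0.8 + 0.6) / 2)

    def test_micro_sensitivity_single_column_prediction(self):
        # all predictions into A, true labels uniform over two categories
        table = vc.confusion_table(
            ["A", "A", "B", "B"], ["A", "A", "A", "A"], ("A", "B")
        )
        _, sens, _ = vc.prf(table, "micro")
        assert sens == pytest.approx(0.5)

    def test_weighted_matches_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(3)
        cats = ("A", "B", "C")
        y_true = rng.choice(cats, size=60)
        y_pred = rng.choice(cats, size=60)
        table = vc.confusion_table(y_true, y_pred, cats)
        for mode in ("weighted", "macro", "micro"):
            expected = precision_recall_fscore_support(
                y_true, y_pred, average=mode, zero_division=0
            )
            got = vc.prf(table, mode)
            np.testing.assert_allclose(got, expected[:3], atol=1e-12)

    def test_zero_support_category_warns(self):
        table = vc.confusion_table(["A", "A"], ["A", "B"], ("A", "B"))
        with pytest.warns(UserWarning, match="zero support"):
            vc.prf(table)

    def test_empty_table_errors(self):
        table = vc.ConfusionTable(np.zeros((2, 2), dtype=int), ("A", "B"))
        with pytest.raises(ValueError):
            vc.prf(table)

    def test_per_category_breakdown(self):
        table = vc.ConfusionTable(np.array([[8, 2], [4, 6]]), ("A", "B"))
        per = per_category_prf(table)
        assert per["A"]["sensitivity"] == pytest.approx(0.8)
        assert per["A"]["precision"] == pytest.approx(8 / 12)
        assert per["B"]["support"] == 10


class TestConcordance:
    def test_all_top1_correct(self):
        assert vc.concordance(["A", "B"], [["A", "B"], ["B", "A"]], k=1) == 1.0

    def test_full_ranking_always_hits(self):
        ranked = [["B", "A", "C"]] * 3
        assert vc.concordance(["A", "C", "B"], ranked, k=3) == 1.0

    def test_none_correct(self):
        assert vc.concordance(["A", "A"], [["B", "A"], ["B", "A"]], k=1) == 0.0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            vc.concordance(["A"], [["A"]], k=0)


class TestPCCC:
    def test_boundary_values(self):
        assert vc.pccc(1.0, 15) == 1.0
        assert vc.pccc(1 / 15, 15) == pytest.approx(0.0)

    def test_worked_example(self):
        assert vc.pccc(0.770, 15, 1) == pytest.approx(0.7536, abs=5e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            vc.pccc(0.5, 1, 1)
        with pytest.raises(ValueError):
            vc.pccc(1.5, 15, 1)


class TestCSMF:
    def test_counting(self):
        np.testing.assert_allclose(
            vc.csmf(["A", "A", "B"], ("A", "B", "C")), [2 / 3, 1 / 3, 0.0]
        )

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["A", "B", "C"], size=50)
        assert vc.csmf(labels, ("A", "B", "C")).sum() == pytest.approx(1.0, abs=1e-9)

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError):
            vc.csmf(["Z"], ("A", "B"))


def oracle_csmfa(true_vec, pred_vec):
    total = sum(abs(p - t) for p, t in zip(pred_vec, true_vec))
    return 1.0 - total / (2.0 * (1.0 - min(true_vec)))


class TestCSMFAccuracy:
    def test_identity_is_one(self):
        v = np.array([0.5, 0.3, 0.2])
        assert vc.csmf_accuracy(v, v) == 1.0

    def test_worked_example(self):
        got = vc.csmf_accuracy(np.array([0.5, 0.3, 0.2]), np.array([0.3, 0.3, 0.4]))
        assert got == pytest.approx(0.75)

    def test_maximal_error_is_zero(self):
        assert vc.csmf_accuracy(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            vc.csmf_accuracy(np.array([1.0]), np.array([0.5, 0.5]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_direct_formula_on_random_simplex_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        t = rng.dirichlet(np.ones(n))
        p = rng.dirichlet(np.ones(n))
        assert vc.csmf_accuracy(t, p) == pytest.approx(oracle_csmfa(t, p), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        t = rng.dirichlet(np.ones(n))
        p = rng.dirichlet(np.ones(n))
        assert -1e-12 <= vc.csmf_accuracy(t, p) <= 1.0 + 1e-12


class TestChanceBaseline:
    def test_single_category_guard(self):
        with pytest.raises(ValueError):
            vc.chance_csmfa("dirichlet_null", n_categories=1)

    def test_dataset_null_two_category_closed_form(self):
        # true distribution (1,0): CSMFA reduces to the fraction predicted
        # into the true category, whose expectation under uniform random
        # assignment is 1/2
        baseline = vc.chance_csmfa(
            "dataset_null",
            true_labels=["A"] * 50,
            categories=("A", "B"),
            iterations=4000,
            seed=5,
        )
        assert baseline.mean == pytest.approx(0.5, abs=0.01)

    def test_reproducible_for_fixed_seed(self):
        kw = dict(mode="dirichlet_null", n_categories=15, iterations=500, seed=9)
        assert vc.chance_csmfa(**kw).mean == vc.chance_csmfa(**kw).mean

    def test_monte_carlo_error_shrinks_with_iterations(self):
        # sample-mean standard error should scale as iterations^(-1/2)
        est = {
            its: np.std(
                [
                    vc.chance_csmfa(
                        "dirichlet_null", n_categories=15, iterations=its, seed=s
                    ).mean
                    for s in range(15)
                ],
                ddof=1,
            )
            for its in (100, 10_000)
        }
        assert est[100] / est[10_000] > 4  # expected ratio ~ 10


class TestCCCSMFA:
    def test_zero_at_chance(self):
        assert vc.cccsmfa(0.643, 0.643) == 0.0

    def test_one_at_perfect(self):
        assert vc.cccsmfa(1.0, 0.643) == pytest.approx(1.0)

    def test_negative_below_chance(self):
        assert vc.cccsmfa(0.5, 0.643) < 0.0

    def test_invalid_chance_mean(self):
        with pytest.raises(ValueError):
            vc.cccsmfa(0.9, 1.0)

    def test_monotone_in_csmfa(self):
        vals = [vc.cccsmfa(a, 0.64) for a in np.linspace(0, 1, 11)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
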