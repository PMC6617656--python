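import json

import numpy as np
import pytest

import vacoder as vc


def small_corpus(seed=5):
    scheme = vc.default_scheme()
    all_categories = scheme.categories("adult") + scheme.categories("neonate")
    lexicons = vc.disjoint_lexicons(all_categories, 6, seed=2)
    cfg = vc.GeneratorConfig(
        scheme=scheme,
        n_per_age_group={"adult": 120, "child": 60, "neonate": 40},
        category_lexicons=lexicons,
        background_weight=0.0,
        misspelling_rate=0.0,
        seed=seed,
    )
    return cfg, vc.generate_corpus(cfg)


class TestFolds:
    def test_folds_partition_each_age_group(self):
        _, corpus = small_corpus()
        plan = vc.make_folds(corpus.records, k=10, seed=1)
        by_group = vc.split_by_age_group(corpus.records)
        for group, folds in plan.test_ids.items():
            ids = [r.record_id for r in by_group[group]]
            union = set().union(*folds)
            assert union == set(ids)
            assert sum(len(f) for f in folds) == len(ids)  # disjoint
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_same_seed_reproduces_plan(self):
        _, corpus = small_corpus()
        a = vc.make_folds(corpus.records, k=10, seed=3)
        b = vc.make_folds(corpus.records, k=10, seed=3)
        assert a == b

    def test_group_smaller_than_k_errors(self):
        records = [
            vc.VARecord(f"r{i}", "adult", "fever", category="Diarrhea")
            for i in range(9)
        ]
        with pytest.raises(ValueError, match="smaller k"):
            vc.make_folds(records, k=10, seed=0)


class TestAugmentation:
    def test_adult_training_includes_all_other_age_groups(self):
        _, corpus = small_corpus()
        plan = vc.make_folds(corpus.records, k=5, seed=0)
        training = vc.assemble_training(plan, 0, "adult", corpus.records)
        ids = {r.record_id for r in training}
        for r in corpus.records:
            if r.age_group in ("child", "neonate"):
                assert r.record_id in ids

    def test_neonate_training_is_neonate_only(self):
        _, corpus = small_corpus()
        plan = vc.make_folds(corpus.records, k=5, seed=0)
        training = vc.assemble_training(plan, 0, "neonate", corpus.records)
        assert all(r.age_group == "neonate" for r in training)

    @pytest.mark.parametrize("group", ["adult", "child", "neonate"])
    def test_training_and_test_sets_are_disjoint(self, group):
        _, corpus = small_corpus()
        plan = vc.make_folds(corpus.records, k=5, seed=0)
        for fold in range(5):
            training = {
                r.record_id
                for r in vc.assemble_training(plan, fold, group, corpus.records)
            }
            assert not training & plan.test_set(group, fold)


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def report_and_corpus(self):
        cfg, corpus = small_corpus()
        lex = vc.Lexicon.default(extra_terms=cfg.all_vocabulary())
        report = vc.run_experiment(
            corpus.records,
            cfg.scheme,
            families=("naive_bayes",),
            k=5,
            seed=11,
            lexicon=lex,
            chance_iterations=1000,
        )
        return report, cfg, corpus

    def test_each_cell_has_exactly_k_fold_entries(self, report_and_corpus):
        report, _, _ = report_and_corpus
        for group in report.age_groups:
            assert len(report.folds[group]["naive_bayes"]) == 5

    def test_means_are_arithmetic_means_of_folds(self, report_and_corpus):
        report, _, _ = report_and_corpus
        vals = report.fold_values("adult", "naive_bayes", "sensitivity")
        assert report.mean("adult", "naive_bayes", "sensitivity") == pytest.approx(
            sum(vals) / len(vals)
        )

    def test_separable_corpus_scores_high(self, report_and_corpus):
        report, _, _ = report_and_corpus
        for group in report.age_groups:
            assert report.mean(group, "naive_bayes", "sensitivity") > 0.9

    def test_rerun_with_same_seed_is_identical(self, report_and_corpus):
        report, cfg, corpus = report_and_corpus
        lex = vc.Lexicon.default(extra_terms=cfg.all_vocabulary())
        again = vc.run_experiment(
            corpus.records,
            cfg.scheme,
            families=("naive_bayes",),
            k=5,
            seed=11,
            lexicon=lex,
            chance_iterations=1000,
        )
        assert again.summary() == report.summary()

    def test_report_json_round_trip(self, report_and_corpus, tmp_path):
        report, _, _ = report_and_corpus
        path = tmp_path / "report.json"
        report.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["k"] == 5
        assert payload["summary"]["adult"]["naive_bayes"]["sensitivity"]["mean"] == (
            pytest.approx(report.mean("adult", "naive_bayes", "sensitivity"))
        )

    def test_unlabeled_record_rejected(self):
        cfg, corpus = small_corpus()
        records = list(corpus.records)
        records[0] = vc.VARecord("bad", "adult", "fever")
        with pytest.raises(ValueError, match="gold category"):
            vc.run_experiment(records, cfg.scheme, families=("naive_bayes",), k=5)


class TestLeakageGuard:
    def test_test_fold_deletion_does_not_change_trained_model(self):
        cfg, corpus = small_corpus()
        stops = vc.StopwordList.default()
        plan = vc.make_folds(corpus.records, k=5, seed=0)
        training = vc.assemble_training(plan, 0, "adult", corpus.records)

        def fit(records_present):
            docs = vc.preprocess_corpus(
                list(records_present),
                vc.Lexicon.default(extra_terms=cfg.all_vocabulary()),
                stops,
            )
            doc_of = {d.record_id: d for d in docs}
            train_docs = [doc_of[r.record_id] for r in training]
            vocab = vc.build_vocabulary(train_docs)
            X = vc.build_feature_matrix(
                train_docs, vocab, [r.age_group for r in training]
            )
            model = vc.train(
                vc.ModelConfig("naive_bayes", seed=1), X, [r.category for r in training]
            )
            return vocab.stems, model.selected_names

        with_test = fit(corpus.records)
        without_test = fit(
            [r for r in corpus.records if r.record_id not in plan.test_set("adult", 0)]
        )
        assert with_test == without_test

    def test_test_only_stem_never_enters_vocabulary(self):
        cfg, corpus = small_corpus()
        plan = vc.make_folds(corpus.records, k=5, seed=0)
        test_ids = plan.test_set("adult", 0)
        records = [
            vc.VARecord(
                r.record_id,
                r.age_group,
                r.narrative + " zzmarkerzz" if r.record_id in test_ids else r.narrative,
                category=r.category,
            )
            for r in corpus.records
        ]
        training = vc.assemble_training(plan, 0, "adult", records)
        stops = vc.StopwordList.default()
        lex = vc.Lexicon.default(extra_terms=list(cfg.all_vocabulary()) + ["zzmarkerzz"])
        docs = vc.preprocess_corpus(training, lex, stops)
        vocab = vc.build_vocabulary(docs)
        assert "zzmarkerzz" not in vocab


class TestReviewFlagging:
    def _preds(self):
        return [
            ("r1", [("A", 0.9), ("B", 0.1)]),
            ("r2", [("B", 0.4), ("A", 0.6)][::-1]),
            ("r3", [("A", 1.0), ("B", 0.0)]),
        ]

    def test_threshold_one_flags_all_but_certain(self):
        flagged = vc.flag_low_confidence(self._preds(), 1.0)
        assert [f[0] for f in flagged] == ["r2", "r1"]  # ascending confidence

    def test_uniform_predictor_fully_flagged(self):
        preds = [(f"r{i}", [("A", 0.5), ("B", 0.5)]) for i in range(4)]
        assert len(vc.flag_low_confidence(preds, 0.51)) == 4

    def test_empty_predictions(self):
        assert vc.flag_low_confidence([], 0.5) == []

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            vc.flag_low_confidence(self._preds(), 0.0)
        with pytest.raises(ValueError):
            vc.flag_low_confidence(self._preds(), 1.5)
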