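"""Corpus construction, features, learners and classifier evaluation."""

import numpy as np
import pytest

from clinrank.classify import (
    CTYPE_NONE,
    DocLabels,
    FeatureConfig,
    LabeledCorpus,
    PositiveRecord,
    build_training_corpus,
    chi2_occurrence,
    evaluate_classifier,
    fit_features,
    map_cancer_type,
    predict_scores,
    prf_report,
    split_train_test,
    train_task_model,
)
from clinrank.corpus_io import Document
from clinrank.synth import GeneratorConfig, generate_corpus

from oracles import brute_chi2_tables


def _doc(i, text):
    return Document(doc_id=str(i), title=text, abstract="")


class TestCorpusConstruction:
    def _positives(self):
        return [
            PositiveRecord(_doc("p1", "braf melanoma therapy"), disease="melanoma",
                           cancer_type="melanoma"),
            PositiveRecord(_doc("p2", "egfr lung response"), disease="lung cancer",
                           cancer_type="lung cancer"),
            PositiveRecord(_doc("p3", "joint inflammation treatment"),
                           disease="rheumatoid arthritis", cancer_type=None,
                           is_cancer=False),
        ]

    def _pool(self):
        pool = [_doc(f"n{i}", f"benign topic number {i}") for i in range(30)]
        pool += [_doc(f"t{i}", f"a tumor growth study {i}") for i in range(5)]
        return pool

    def test_label_assignment_rules(self):
        corpus = build_training_corpus(
            self._positives(), self._pool(), ["tumor", "cancer"], n_negatives=10, seed=0
        )
        by_id = dict(zip((d.doc_id for d in corpus.documents), corpus.labels))
        # flagged non-cancer positive: clinical=+ but cancer=-
        assert by_id["p3"] == DocLabels(cancer=False, clinical=True, ctype=CTYPE_NONE)
        # named type kept; unnamed cancer type folded into general_cancer
        assert by_id["p1"].ctype == "melanoma"
        assert by_id["p2"].ctype == "general_cancer"
        # all positives clinical=+
        assert all(by_id[f"p{i}"].clinical for i in (1, 2, 3))

    def test_term_containing_pool_docs_never_sampled(self):
        corpus = build_training_corpus(
            self._positives(), self._pool(), ["tumor"], n_negatives=30, seed=1
        )
        neg_ids = {d.doc_id for d, lab in zip(corpus.documents, corpus.labels)
                   if not lab.clinical}
        assert all(i.startswith("n") for i in neg_ids)
        assert len(neg_ids) == 30

    def test_insufficient_pool_reports_available_count(self):
        with pytest.raises(ValueError, match="30 available"):
            build_training_corpus(self._positives(), self._pool(), ["tumor"],
                                  n_negatives=31, seed=0)

    def test_type_mapping_table(self):
        assert map_cancer_type("Head and Neck") == "head_and_neck"
        assert map_cancer_type("Colorectal Cancer") == "colorectal"
        assert map_cancer_type("glioblastoma") == "general_cancer"


class TestSplit:
    def _corpus(self, n_pos=50, n_neg=50):
        docs, labels = [], []
        for i in range(n_pos):
            docs.append(_doc(f"p{i}", "pos"))
            labels.append(DocLabels(True, True, "general_cancer"))
        for i in range(n_neg):
            docs.append(_doc(f"n{i}", "neg"))
            labels.append(DocLabels(False, False, CTYPE_NONE))
        return LabeledCorpus(docs, labels)

    def test_stratified_sizes_within_one(self):
        train, test = split_train_test(self._corpus(), seed=3)
        assert len(train) + len(test) == 100
        pos_train = sum(1 for lab in train.labels if lab.cancer)
        assert pos_train in (42, 43)
        assert len(train) in (84, 85, 86)

    def test_disjoint_and_deterministic(self):
        c = self._corpus()
        t1, s1 = split_train_test(c, seed=5)
        t2, s2 = split_train_test(c, seed=5)
        assert [d.doc_id for d in t1.documents] == [d.doc_id for d in t2.documents]
        assert not ({d.doc_id for d in t1.documents} & {d.doc_id for d in s1.documents})

    def test_degenerate_fraction_is_error(self):
        with pytest.raises(ValueError):
            split_train_test(self._corpus(), train_fraction=1.0, seed=0)

    def test_tiny_stratum_is_error(self):
        with pytest.raises(ValueError, match="stratum"):
            split_train_test(self._corpus(n_pos=1), seed=0)


class TestFeatures:
    def test_idf_is_one_for_ubiquitous_term(self):
        texts = ["alpha beta", "alpha gamma", "alpha delta"]
        feats = fit_features(texts, FeatureConfig(ngram_range=(1, 1), min_doc_freq=1),
                             [0, 1, 1])
        vocab = feats.vectorizer.vocabulary_
        # ln((1+N)/(1+df)) + 1 = ln(1) + 1 for df == N
        assert feats.vectorizer.idf_[vocab["alpha"]] == pytest.approx(1.0)

    def test_vectors_unit_norm_or_zero(self, small_bundle):
        corpus = small_bundle.labeled_corpus()
        feats = fit_features(corpus.texts()[:100],
                             FeatureConfig(ngram_range=(1, 1), min_doc_freq=1,
                                           max_features_chi2=50),
                             corpus.task_labels("cancer")[:100])
        X = feats.transform(corpus.texts())
        norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
        assert np.all((np.abs(norms - 1) < 1e-9) | (norms == 0))
        assert (norms == 0).any() or True  # zero rows allowed, not required

    def test_chi2_matches_contingency_oracle_small_vocab(self):
        rng = np.random.default_rng(0)
        present = (rng.random((40, 9)) < 0.4).astype(int)
        y = rng.integers(0, 2, size=40)
        ours = chi2_occurrence(present, y)
        ref = brute_chi2_tables(present.tolist(), y.tolist())
        assert np.allclose(ours, ref, atol=1e-9)

    def test_chi2_multiclass_matches_oracle(self):
        rng = np.random.default_rng(1)
        present = (rng.random((60, 7)) < 0.5).astype(int)
        y = rng.integers(0, 3, size=60)
        assert np.allclose(chi2_occurrence(present, y),
                           brute_chi2_tables(present.tolist(), y.tolist()), atol=1e-9)

    def test_class_exclusive_term_has_maximal_chi2(self):
        texts = ["tumor drug", "tumor trial", "weather rain", "weather sun"]
        y = [1, 1, 0, 0]
        feats = fit_features(texts, FeatureConfig(ngram_range=(1, 1), min_doc_freq=1), y)
        scores = dict(zip(feats.vectorizer.get_feature_names_out(), feats.chi2_scores))
        assert scores["tumor"] == max(scores.values())

    def test_k_larger_than_vocabulary_keeps_all(self):
        feats = fit_features(["aa bb cc", "cc dd ee"],
                             FeatureConfig(ngram_range=(1, 1), min_doc_freq=1,
                                           max_features_chi2=10_000),
                             [0, 1])
        assert len(feats.mask) == len(feats.vectorizer.vocabulary_)

    def test_empty_vocabulary_is_error(self):
        with pytest.raises(ValueError, match="vocabulary"):
            fit_features(["a b", "c d"], FeatureConfig(min_doc_freq=5), [0, 1])


@pytest.fixture(scope="module")
def separable_split():
    bundle = generate_corpus(GeneratorConfig(n_docs=300, overlap=0.0, seed=2))
    return split_train_test(bundle.labeled_corpus(), seed=2)


CFG = FeatureConfig(ngram_range=(1, 1), min_doc_freq=1, max_features_chi2=2000)


class TestTraining:
    def test_separable_corpus_reaches_perfect_cv_f1(self, separable_split):
        train, _ = separable_split
        model = train_task_model("cancer", "linear_svm", train, CFG,
                                 search_budget=3, seed=0)
        assert model.best_cv_score == pytest.approx(1.0)

    def test_same_seed_same_hyperparameters(self, separable_split):
        train, _ = separable_split
        m1 = train_task_model("clinical", "linear_svm", train, CFG, search_budget=4, seed=9)
        m2 = train_task_model("clinical", "linear_svm", train, CFG, search_budget=4, seed=9)
        assert m1.best_params == m2.best_params
        assert m1.raw_min == m2.raw_min and m1.raw_max == m2.raw_max

    def test_budget_one_trains_single_configuration(self, separable_split):
        train, _ = separable_split
        model = train_task_model("cancer", "linear_svm", train, CFG,
                                 search_budget=1, seed=0)
        assert set(model.best_params) == {"C"}

    def test_class_below_five_examples_is_error(self):
        docs = [_doc(i, "x y") for i in range(10)]
        labels = [DocLabels(i < 3, i < 3, CTYPE_NONE if i >= 3 else "melanoma")
                  for i in range(10)]
        with pytest.raises(ValueError, match="<5"):
            train_task_model("cancer", "linear_svm", LabeledCorpus(docs, labels),
                             CFG, seed=0)

    def test_model_save_load_round_trip(self, separable_split, tmp_path):
        train, test = separable_split
        model = train_task_model("cancer", "linear_svm", train, CFG,
                                 search_budget=2, seed=1)
        model.save(tmp_path / "m")
        from clinrank.classify import TaskModel

        loaded = TaskModel.load(tmp_path / "m")
        texts = test.texts()[:20]
        assert np.allclose(loaded.raw_scores(texts), model.raw_scores(texts))


@pytest.fixture(scope="module")
def models(separable_split):
    train, _ = separable_split
    return {
        task: train_task_model(task, "linear_svm", train, CFG,
                               search_budget=2, seed=0)
        for task in ("cancer", "clinical", "ctype")
    }


class TestPrediction:
    def test_scores_finite_and_deterministic(self, separable_split, models):
        _, test = separable_split
        doc = test.documents[0]
        out1 = predict_scores(models, doc)
        out2 = predict_scores(models, doc)
        assert out1 == out2
        assert np.isfinite(out1["cancer_raw"]) and np.isfinite(out1["clinical_raw"])
        assert out1["ctype_label"] in ("melanoma", "head_and_neck", "colorectal",
                                       "general_cancer")

    def test_empty_abstract_scored_on_title(self, models):
        doc = Document("t", "some title only", "")
        out = predict_scores(models, doc)
        assert np.isfinite(out["cancer_raw"])


class TestEvaluation:
    def test_confusion_counts_formula(self):
        # TP=2 FP=1 FN=1 for class 1
        y_true = np.array([1, 1, 1, 0, 0])
        y_pred = np.array([1, 1, 0, 1, 0])
        rep = prf_report(y_true, y_pred, [0, 1])
        assert rep["per_class"]["1"]["precision"] == pytest.approx(2 / 3)
        assert rep["per_class"]["1"]["recall"] == pytest.approx(2 / 3)
        assert rep["per_class"]["1"]["f1"] == pytest.approx(2 / 3)

    def test_perfect_and_inverted_predictions(self):
        y = np.array([0, 1, 0, 1])
        assert prf_report(y, y, [0, 1])["macro"]["f1"] == pytest.approx(1.0)
        assert prf_report(y, 1 - y, [0, 1])["macro"]["f1"] == pytest.approx(0.0)

    def test_class_absent_from_test_reported_null(self):
        y_true = np.array([0, 0, 0])
        y_pred = np.array([0, 0, 1])
        rep = prf_report(y_true, y_pred, [0, 1, 2])
        assert rep["per_class"]["2"] == {"precision": None, "recall": None, "f1": None}

    def test_end_to_end_evaluation_on_separable_data(self, separable_split):
        train, test = separable_split
        model = train_task_model("cancer", "linear_svm", train, CFG,
                                 search_budget=2, seed=0)
        rep = evaluate_classifier(model, test)
        assert rep["macro"]["f1"] >= 0.95
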