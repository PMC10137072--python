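"""Bernoulli naive Bayes: fit, predict, cross-validation, corpus triage."""

from fractions import Fraction
from itertools import product

import numpy as np
import pytest

from levelmap import Category
from levelmap.naive_bayes import (
    balanced_accuracy,
    classify_corpus,
    cross_validate,
    fit,
    model_from_json,
    model_to_json,
    predict,
    tokenize_distinct,
)

AURORA_SENTENCE = (
    "Using IP with an anti-acetyl lysine antibody, we identified Aurora B as "
    "an acetylated protein in PC3 prostate cancer cells."
)


class TestTokenize:
    def test_repeated_words_contribute_once(self):
        assert tokenize_distinct("Gene gene GENE") == {"gene"}

    def test_empty_text(self):
        assert tokenize_distinct("") == frozenset()

    def test_hand_tokenization_of_review_example(self):
        expected = {
            "using", "ip", "with", "an", "anti", "acetyl", "lysine",
            "antibody", "we", "identified", "aurora", "b", "as",
            "acetylated", "protein", "in", "pc3", "prostate", "cancer",
            "cells",
        }
        assert tokenize_distinct(AURORA_SENTENCE) == expected


def oracle_posterior(labeled, doc_tokens, alpha=1):
    """Exact-rational Bayes posterior from raw counts (independent path).

    Computes P(+|doc) by explicit products of smoothed Bernoulli
    likelihood factors over the training vocabulary, in Fraction
    arithmetic; no logs, no shared code with the implementation.
    """
    vocab = sorted({t for tokens, _ in labeled for t in tokens})
    n_pos = sum(1 for _, y in labeled if y)
    n_neg = len(labeled) - n_pos
    scores = {}
    for cls, n_cls in ((True, n_pos), (False, n_neg)):
        score = Fraction(n_cls, len(labeled))
        for t in vocab:
            df = sum(1 for tokens, y in labeled if y == cls and t in tokens)
            p = Fraction(df + alpha, n_cls + 2 * alpha)
            score *= p if t in doc_tokens else 1 - p
        scores[cls] = score
    return scores[True] / (scores[True] + scores[False])


class TestFit:
    def test_two_document_closed_form(self):
        model = fit([({"a"}, True), ({"b"}, False)], alpha=1.0)
        assert model.prior_positive == 0.5
        assert model.p_pos["a"] == pytest.approx(2 / 3)
        assert model.p_neg["a"] == pytest.approx(1 / 3)

    def test_swapped_labels_mirror_parameters(self):
        data = [({"a", "b"}, True), ({"b"}, True), ({"c"}, False)]
        swapped = [(tokens, not y) for tokens, y in data]
        m1, m2 = fit(data), fit(swapped)
        assert m1.prior_positive == pytest.approx(1 - m2.prior_positive)
        assert m1.p_pos == m2.p_neg and m1.p_neg == m2.p_pos

    def test_four_document_hand_table(self):
        corpus = [({"a", "b"}, True), ({"a"}, True), ({"b", "c"}, False), ({"c"}, False)]
        model = fit(corpus, alpha=1.0)
        assert model.p_pos == pytest.approx({"a": 3 / 4, "b": 1 / 2, "c": 1 / 4})
        assert model.p_neg == pytest.approx({"a": 1 / 4, "b": 1 / 2, "c": 3 / 4})

    def test_single_class_is_fatal(self):
        with pytest.raises(ValueError):
            fit([({"a"}, True), ({"b"}, True)])

    def test_nonpositive_alpha_is_fatal(self):
        with pytest.raises(ValueError):
            fit([({"a"}, True), ({"b"}, False)], alpha=0.0)


class TestPredict:
    def test_tie_goes_negative(self):
        model = fit([({"a"}, True), ({"b"}, False)], alpha=1.0)
        label, posterior = predict(model, set())
        assert posterior == pytest.approx(0.5)
        assert label is False

    def test_four_document_hand_posterior(self):
        corpus = [({"a", "b"}, True), ({"a"}, True), ({"b", "c"}, False), ({"c"}, False)]
        model = fit(corpus, alpha=1.0)
        label, posterior = predict(model, {"a"})
        # by hand: score+ = .5*(3/4)(1/2)(3/4), score- = .5*(1/4)(1/2)(1/4)
        assert posterior == pytest.approx(0.9)
        assert label is True

    def test_duplicate_words_in_raw_text_do_not_matter(self):
        corpus = [({"a", "b"}, True), ({"c"}, False)] * 3
        model = fit(corpus)
        assert predict(model, tokenize_distinct("a a a b")) == predict(
            model, tokenize_distinct("a b")
        )

    def test_out_of_vocabulary_tokens_ignored(self):
        model = fit([({"a"}, True), ({"b"}, False)])
        assert predict(model, {"a", "zzz"}) == predict(model, {"a"})

    def test_posteriors_of_both_classes_sum_to_one(self):
        model = fit([({"a", "b"}, True), ({"b"}, False), ({"c"}, False)])
        _, p_pos = predict(model, {"a", "c"})
        swapped = fit([({"a", "b"}, False), ({"b"}, True), ({"c"}, True)])
        _, p_neg = predict(swapped, {"a", "c"})
        assert p_pos + p_neg == pytest.approx(1.0, abs=1e-12)

    def test_matches_exact_bayes_oracle_on_random_corpora(self):
        rng = np.random.default_rng(42)
        vocab = list("abcdef")
        for _ in range(50):
            n_docs = int(rng.integers(4, 12))
            labeled = []
            while True:
                labeled = [
                    (
                        frozenset(
                            t for t in vocab if rng.random() < 0.4
                        ),
                        bool(rng.random() < 0.5),
                    )
                    for _ in range(n_docs)
                ]
                labels = {y for _, y in labeled}
                if labels == {True, False}:
                    break
            model = fit(labeled, alpha=1.0)
            doc = frozenset(t for t in vocab if rng.random() < 0.4)
            _, posterior = predict(model, doc)
            expected = oracle_posterior(labeled, doc)
            assert abs(posterior - float(expected)) < 1e-10

    def test_agrees_with_sklearn_bernoulli_nb(self):
        from sklearn.naive_bayes import BernoulliNB

        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(20, 5))
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]  # ensure both classes
        vocab = [f"t{j}" for j in range(5)]
        labeled = [
            (frozenset(v for j, v in enumerate(vocab) if X[i, j]), bool(y[i]))
            for i in range(20)
        ]
        model = fit(labeled, alpha=1.0)
        sk = BernoulliNB(alpha=1.0).fit(X, y)
        for row in product([0, 1], repeat=5):
            doc = frozenset(v for j, v in enumerate(vocab) if row[j])
            _, posterior = predict(model, doc)
            sk_posterior = sk.predict_proba(np.array(row).reshape(1, -1))[0, 1]
            assert posterior == pytest.approx(sk_posterior, abs=1e-10)


class TestBalancedAccuracy:
    def test_constant_classifier_scores_half(self):
        y_true = [True] * 9 + [False]
        assert balanced_accuracy(y_true, [True] * 10) == 0.5
        assert balanced_accuracy(y_true, [False] * 10) == 0.5

    def test_perfect_and_inverted(self):
        y = [True, False, True, False]
        assert balanced_accuracy(y, y) == 1.0
        assert balanced_accuracy(y, [not v for v in y]) == 0.0

    def test_single_class_truth_is_fatal(self):
        with pytest.raises(ValueError):
            balanced_accuracy([True, True], [True, False])


def separable_set(n=40):
    return [
        (f"f{i}", frozenset({"pos"} if i % 2 == 0 else {"neg"}), i % 2 == 0)
        for i in range(n)
    ]


class TestCrossValidate:
    def test_perfectly_separable_scores_one(self):
        report = cross_validate(separable_set(), seed=0)
        assert report.mean_balanced_accuracy == pytest.approx(1.0)

    def test_folds_partition_and_stratify(self):
        labeled = separable_set(50)
        report = cross_validate(labeled, folds=5, seed=1)
        assert sorted(report.fold_assignments) == sorted(f for f, _, _ in labeled)
        folds = np.array([report.fold_assignments[f"f{i}"] for i in range(50)])
        labels = np.array([i % 2 == 0 for i in range(50)])
        for fold in range(1, 6):
            in_fold = folds == fold
            assert abs(labels[in_fold].sum() - (~labels[in_fold]).sum()) <= 1

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(0)
        scores = []
        for rep in range(50):
            tokens = [
                frozenset({"pos"} if i % 2 == 0 else {"neg"}) for i in range(60)
            ]
            labels = rng.permutation([i % 2 == 0 for i in range(60)])
            labeled = [
                (f"f{i}", tokens[i], bool(labels[i])) for i in range(60)
            ]
            scores.append(cross_validate(labeled, seed=rep).mean_balanced_accuracy)
        assert np.mean(scores) == pytest.approx(0.5, abs=0.05)

    def test_reproducible_and_order_invariant_for_fixed_seed(self):
        labeled = separable_set(30)
        a = cross_validate(labeled, seed=7)
        b = cross_validate(labeled[::-1], seed=7)
        assert a.fold_assignments == b.fold_assignments
        assert a.mean_balanced_accuracy == b.mean_balanced_accuracy

    def test_class_too_small_is_fatal(self):
        labeled = [("a", frozenset("x"), True)] * 4 + [("b", frozenset("y"), False)] * 8
        with pytest.raises(ValueError):
            cross_validate(labeled, folds=5)


class TestClassifyCorpus:
    def test_counts_partition_each_category(self):
        model = fit([({"pos"}, True), ({"neg"}, False)] * 5)
        screened = {
            Category.PROTEIN: [
                (f"f{i}", frozenset({"pos"} if i % 3 else {"neg"})) for i in range(9)
            ]
        }
        summary = classify_corpus({Category.PROTEIN: model}, screened)[Category.PROTEIN]
        assert summary.confirmed_count + summary.unrelated_count == 9

    def test_all_positive_model_gives_zero_unrelated(self):
        model = fit([({"pos"}, True), ({"pos"}, True), ({"rare_negative_token"}, False)])
        screened = {Category.DNA_RNA: [(f"f{i}", frozenset({"pos"})) for i in range(4)]}
        summary = classify_corpus({Category.DNA_RNA: model}, screened)[Category.DNA_RNA]
        assert summary.unrelated_count == 0


def test_model_json_round_trip():
    model = fit([({"a", "b"}, True), ({"c"}, False)], category=Category.PROTEIN)
    restored = model_from_json(model_to_json(model))
    assert restored.p_pos == model.p_pos
    assert restored.p_neg == model.p_neg
    assert restored.prior_positive == model.prior_positive
    assert restored.category == model.category
    assert predict(restored, {"a"}) == predict(model, {"a"})


def test_multinomial_event_model_uses_counts():
    from collections import Counter

    labeled = [
        (Counter({"a": 3, "b": 1}), True),
        (Counter({"b": 4}), False),
    ]
    model = fit(labeled, alpha=1.0, event_model="multinomial")
    # P(a|+) = (3+1)/(4+2*1)... vocabulary {a,b}: (3+1)/(4+2) = 2/3
    assert model.p_pos["a"] == pytest.approx(4 / 6)
    assert model.p_neg["a"] == pytest.approx(1 / 6)
    label, _ = predict(model, {"a"})
    assert label is True
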