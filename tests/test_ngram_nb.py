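"""N-gram extraction, multinomial Naive Bayes, and feature reports."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_stream
from ehrwin.ngram_nb import (
    classify,
    distinctiveness_threshold,
    extract_ngrams,
    fit_nb,
    top_informative,
)

SENTENCE = ["the", "patient", "is", "not", "suicidal", "."]


class TestExtractNgrams:
    def test_bigrams_of_worked_sentence(self):
        assert extract_ngrams(SENTENCE, 2) == [
            "the patient", "patient is", "is not", "not suicidal", "suicidal .",
        ]

    def test_trigrams_of_worked_sentence(self):
        grams = extract_ngrams(SENTENCE, 3)
        assert len(grams) == 4
        assert grams[0] == "the patient is"

    def test_short_document_yields_empty(self):
        assert extract_ngrams(["overdose"], 2) == []
        assert extract_ngrams([], 1) == []

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            extract_ngrams(SENTENCE, 0)

    @given(st.lists(st.sampled_from("abcd"), max_size=30), st.integers(1, 4))
    def test_count_conservation(self, tokens, n):
        assert len(extract_ngrams(tokens, n)) == max(0, len(tokens) - n + 1)


def _toy_streams():
    return [
        make_stream("p0", ["overdose", "risk"], "proximal"),
        make_stream("p1", ["overdose"], "proximal"),
        make_stream("d0", ["plan"], "distal"),
        make_stream("d1", ["plan", "care"], "distal"),
    ]


class TestFit:
    def test_hand_computed_smoothed_likelihoods(self):
        """4-document unigram fixture, alpha = 1, |V| = 4, class totals 3:
        every likelihood equals (count + 1) / (3 + 4) computed by hand."""
        model = fit_nb(_toy_streams(), n=1, alpha=1.0)
        lik = {
            (c, f): math.exp(model.log_likelihood[c][model.index[f]])
            for c in ("proximal", "distal")
            for f in model.vocabulary
        }
        assert lik[("proximal", "overdose")] == pytest.approx(3 / 7)
        assert lik[("proximal", "risk")] == pytest.approx(2 / 7)
        assert lik[("proximal", "plan")] == pytest.approx(1 / 7)
        assert lik[("distal", "plan")] == pytest.approx(3 / 7)
        assert lik[("distal", "care")] == pytest.approx(2 / 7)
        assert lik[("distal", "overdose")] == pytest.approx(1 / 7)

    def test_balanced_classes_equal_priors(self):
        model = fit_nb(_toy_streams(), n=1)
        assert model.log_prior["proximal"] == model.log_prior["distal"]

    def test_one_class_exclusive_feature_ordering(self):
        model = fit_nb(_toy_streams(), n=1)
        i = model.index["overdose"]
        assert model.log_likelihood["proximal"][i] > model.log_likelihood["distal"][i]

    def test_likelihoods_normalised(self):
        model = fit_nb(_toy_streams(), n=1)
        for c in ("proximal", "distal"):
            assert np.exp(model.log_likelihood[c]).sum() == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_nb([make_stream("p0", ["a", "b"], "proximal")], n=1)

    def test_alpha_to_zero_approaches_ml_ratio(self):
        streams = [
            make_stream("p0", ["a", "a", "b"], "proximal"),
            make_stream("d0", ["a", "b", "b"], "distal"),
        ]
        model = fit_nb(streams, n=1, alpha=1e-9)
        i = model.index["a"]
        assert math.exp(model.log_likelihood["proximal"][i]) == pytest.approx(
            2 / 3, rel=1e-6
        )


def _brute_force_posterior(streams, tokens, n, alpha=1):
    """Independent exact-rational posterior computation."""
    from collections import Counter

    vocab = sorted({g for s in streams for g in extract_ngrams(s.tokens, n)})
    counts = {"proximal": Counter(), "distal": Counter()}
    docs = {"proximal": 0, "distal": 0}
    for s in streams:
        docs[s.period] += 1
        counts[s.period].update(extract_ngrams(s.tokens, n))
    scores = {}
    for c in ("proximal", "distal"):
        score = Fraction(docs[c], sum(docs.values()))
        denom = sum(counts[c].values()) + alpha * len(vocab)
        for g in extract_ngrams(tokens, n):
            if g in vocab:
                score *= Fraction(counts[c][g] + alpha, denom)
        scores[c] = score
    return scores


class TestClassify:
    def test_empty_stream_ties_to_distal(self):
        label, log_odds = classify(fit_nb(_toy_streams(), n=1), [])
        assert label == "distal" and log_odds == 0.0

    def test_proximal_exclusive_features(self):
        model = fit_nb(_toy_streams(), n=1)
        label, log_odds = classify(model, ["overdose", "risk"])
        assert label == "proximal" and log_odds > 0

    def test_out_of_vocabulary_ignored(self):
        model = fit_nb(_toy_streams(), n=1)
        assert classify(model, ["zzz"])[1] == 0.0

    def test_matches_brute_force_posterior_on_fixture(self):
        """Labels and log-odds agree with an exact-rational independent
        posterior computation on a 10-document fixture."""
        rng = np.random.default_rng(2)
        vocab = ["a", "b", "c", "d", "e"]
        streams = [
            make_stream(
                f"s{i}",
                list(rng.choice(vocab, size=rng.integers(2, 8))),
                "proximal" if i < 5 else "distal",
            )
            for i in range(10)
        ]
        model = fit_nb(streams, n=1)
        for s in streams:
            label, log_odds = classify(model, s.tokens)
            scores = _brute_force_posterior(streams, s.tokens, 1)
            expected = (
                "proximal" if scores["proximal"] > scores["distal"] else "distal"
            )
            assert label == expected
            assert log_odds == pytest.approx(
                math.log(scores["proximal"] / scores["distal"]), rel=1e-9
            )

    def test_matches_sklearn_reference(self):
        """Cross-check fitted likelihoods and labels against scikit-learn's
        multinomial NB on a random bigram problem."""
        from sklearn.naive_bayes import MultinomialNB

        rng = np.random.default_rng(4)
        vocab = ["a", "b", "c", "d"]
        streams = [
            make_stream(
                f"s{i}",
                list(rng.choice(vocab, size=rng.integers(3, 10))),
                "proximal" if i % 2 else "distal",
            )
            for i in range(12)
        ]
        model = fit_nb(streams, n=2, alpha=1.0)
        features = model.vocabulary
        x = np.zeros((len(streams), len(features)), dtype=int)
        for r, s in enumerate(streams):
            for g in extract_ngrams(s.tokens, 2):
                x[r, model.index[g]] += 1
        y = [s.period for s in streams]
        ref = MultinomialNB(alpha=1.0).fit(x, y)
        ours = np.vstack(
            [model.log_likelihood[c] for c in ref.classes_]
        )
        assert np.allclose(ours, ref.feature_log_prob_)
        our_labels = [classify(model, s.tokens)[0] for s in streams]
        assert our_labels == list(ref.predict(x))

    def test_label_swap_negates_log_odds(self):
        streams = _toy_streams()
        flip = {"proximal": "distal", "distal": "proximal"}
        swapped = [
            make_stream(s.doc_id, s.tokens, flip[s.period]) for s in streams
        ]
        m1, m2 = fit_nb(streams, n=1), fit_nb(swapped, n=1)
        for tokens in (["overdose"], ["plan", "care"], ["risk", "plan"]):
            assert classify(m2, tokens)[1] == pytest.approx(
                -classify(m1, tokens)[1], rel=1e-12
            )


class TestTopInformative:
    def test_uninformative_feature_ranked_last(self):
        streams = [
            make_stream("p0", ["same", "up"], "proximal"),
            make_stream("d0", ["same", "down"], "distal"),
        ]
        model = fit_nb(streams, n=1)
        reports = top_informative(model, streams, k=3, compute_t_star=False)
        assert reports[-1].feature == "same"
        assert reports[-1].informativeness == pytest.approx(0.0)

    def test_k_capped_at_vocabulary(self):
        streams = _toy_streams()
        model = fit_nb(streams, n=1)
        reports = top_informative(model, streams, k=1000, compute_t_star=False)
        assert len(reports) == len(model.vocabulary)

    def test_rank_is_stable_total_order(self):
        streams = _toy_streams()
        model = fit_nb(streams, n=1)
        r1 = top_informative(model, streams, k=4, compute_t_star=False)
        r2 = top_informative(model, streams, k=4, compute_t_star=False)
        assert [r.feature for r in r1] == [r.feature for r in r2]

    def test_mean_frequency_over_whole_corpus(self):
        streams = _toy_streams()
        model = fit_nb(streams, n=1)
        reports = {r.feature: r for r in top_informative(model, streams, k=10)}
        assert reports["overdose"].mean_freq_per_doc == pytest.approx(2 / 4)

    def test_enriched_period_direction(self):
        streams = _toy_streams()
        model = fit_nb(streams, n=1)
        reports = {r.feature: r for r in top_informative(model, streams, k=10)}
        assert reports["overdose"].enriched_period == "proximal"
        assert reports["plan"].enriched_period == "distal"


class TestDistinctivenessThreshold:
    def test_perfect_separator_threshold_one(self):
        streams = [
            make_stream(f"p{i}", ["risk", "x"], "proximal") for i in range(12)
        ] + [make_stream(f"d{i}", ["x"], "distal") for i in range(12)]
        assert distinctiveness_threshold("risk", streams) == 1

    def test_identical_distributions_absent(self):
        streams = [
            make_stream(f"p{i}", ["x", "x"], "proximal") for i in range(10)
        ] + [make_stream(f"d{i}", ["x", "x"], "distal") for i in range(10)]
        assert distinctiveness_threshold("x", streams) is None

    def test_count_based_separation_matches_brute_scan(self):
        """Only high per-document counts separate the classes: t* must equal
        an exhaustive scan using scipy directly."""
        from scipy import stats as sps

        prox = [make_stream(f"p{i}", ["of"] * 7 + ["x"], "proximal") for i in range(15)]
        dist = [make_stream(f"d{i}", ["of"] * 2 + ["x"], "distal") for i in range(15)]
        streams = prox + dist
        got = distinctiveness_threshold("of", streams)

        counts = {
            "proximal": [s.tokens.count("of") for s in prox],
            "distal": [s.tokens.count("of") for s in dist],
        }
        expected = None
        for t in range(1, 8):
            a = sum(c >= t for c in counts["proximal"])
            c_ = sum(c >= t for c in counts["distal"])
            b, d = 15 - a, 15 - c_
            aa, bb, cc, dd = (
                (a + 0.5, b + 0.5, c_ + 0.5, d + 0.5) if 0 in (a, b, c_, d) else (a, b, c_, d)
            )
            orr = (aa * dd) / (bb * cc)
            p = sps.fisher_exact([[a, b], [c_, d]]).pvalue
            if (orr < 0.66 or orr > 1.50) and p <= 0.05:
                expected = t
                break
        assert got == expected == 3
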