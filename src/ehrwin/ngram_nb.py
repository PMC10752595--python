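"""N-gram featurisation, multinomial Naive Bayes, and feature reports.

Documents are represented as bags of uni-, bi- or tri-grams over the
lemmatised token stream (function words and punctuation retained).  A
two-class multinomial Naive Bayes model is fitted per representation:

* class prior = class share of documents;
* feature likelihood = (class count of the feature + alpha) /
  (class total n-grams + alpha * |V|), with additive smoothing alpha = 1.

The model is fitted on the full corpus for descriptive feature inspection
(no held-out evaluation is implied).  A feature's *informativeness* is the
absolute difference of its class log-likelihoods — how strongly one
occurrence shifts the document's log-odds.  The top-k report adds, per
feature, the document-presence odds ratio, the mean occurrences per document
over the whole corpus, and the *distinctiveness threshold* t*: the smallest
per-document count at which the indicator "count >= t" passes the word
retention gates (p <= 0.05 and OR outside (0.66, 1.50)).  For very common
function words t* can be large — presence alone says nothing, but unusually
many repetitions do.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .text_prep import TokenStream
from .word_discrimination import TwoByTwo, odds_ratio, p_value

logger = logging.getLogger(__name__)

__all__ = [
    "NgramModel",
    "FeatureReport",
    "extract_ngrams",
    "fit_nb",
    "classify",
    "top_informative",
    "distinctiveness_threshold",
    "feature_report_frame",
]

CLASSES = ("proximal", "distal")


def extract_ngrams(tokens: Sequence[str], n: int) -> list[str]:
    """All contiguous length-n windows, in order, duplicates included.

    N-grams are token sequences joined by single spaces.  A document with
    fewer than n tokens yields an empty list.  Raises for ``n < 1``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if len(tokens) < n:
        return []
    if n == 1:
        return list(tokens)
    return [" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


@dataclass
class NgramModel:
    """Fitted two-class multinomial Naive Bayes over an n-gram vocabulary."""

    n: int
    alpha: float
    vocabulary: list[str]  # stable feature order (first-seen)
    index: dict[str, int] = field(repr=False)
    log_prior: dict[str, float]  # class -> log prior
    log_likelihood: dict[str, np.ndarray]  # class -> per-feature log P(f|class)
    class_feature_counts: dict[str, np.ndarray]  # raw per-class counts
    n_docs: dict[str, int]


def fit_nb(
    streams: Iterable[TokenStream], n: int, alpha: float = 1.0
) -> NgramModel:
    """Fit the multinomial model on labelled n-gram streams.

    Raises ``ValueError`` when either class is unrepresented (a single-class
    corpus has no likelihood contrast to learn).
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    vocab: list[str] = []
    index: dict[str, int] = {}
    counts = {c: [] for c in CLASSES}
    n_docs = {c: 0 for c in CLASSES}
    doc_features: list[tuple[str, list[int]]] = []

    for stream in streams:
        if stream.period not in n_docs:
            raise ValueError(f"stream {stream.doc_id!r} has period {stream.period!r}")
        n_docs[stream.period] += 1
        feats = []
        for g in extract_ngrams(stream.tokens, n):
            idx = index.get(g)
            if idx is None:
                idx = index[g] = len(vocab)
                vocab.append(g)
            feats.append(idx)
        doc_features.append((stream.period, feats))

    if min(n_docs.values()) == 0:
        raise ValueError(f"single-class corpus: {n_docs}")

    v = len(vocab)
    count_arr = {c: np.zeros(v, dtype=np.int64) for c in CLASSES}
    for period, feats in doc_features:
        np.add.at(count_arr[period], feats, 1)

    total = sum(n_docs.values())
    log_prior = {c: math.log(n_docs[c] / total) for c in CLASSES}
    log_lik = {}
    for c in CLASSES:
        denom = count_arr[c].sum() + alpha * v
        with np.errstate(divide="ignore"):
            log_lik[c] = np.log((count_arr[c] + alpha) / denom)
    return NgramModel(
        n=n,
        alpha=alpha,
        vocabulary=vocab,
        index=index,
        log_prior=log_prior,
        log_likelihood=log_lik,
        class_feature_counts=count_arr,
        n_docs=dict(n_docs),
    )


def classify(model: NgramModel, tokens: Sequence[str]) -> tuple[str, float]:
    """Classify one document; returns (label, proximal-minus-distal log-odds).

    Out-of-vocabulary n-grams are ignored.  An exact tie (including the
    empty-document / equal-prior case) resolves to "distal", the reference
    class.
    """
    scores = {c: model.log_prior[c] for c in CLASSES}
    for g in extract_ngrams(tokens, model.n):
        idx = model.index.get(g)
        if idx is None:
            continue
        for c in CLASSES:
            scores[c] += float(model.log_likelihood[c][idx])
    log_odds = scores["proximal"] - scores["distal"]
    label = "proximal" if log_odds > 0 else "distal"
    return label, log_odds


@dataclass
class FeatureReport:
    feature: str
    n: int
    informativeness: float
    enriched_period: str  # class with the higher likelihood
    odds_ratio: float
    p_value: float
    mean_freq_per_doc: float
    t_star: Optional[int]


def _doc_counts(streams: Sequence[TokenStream], feature: str, n: int) -> dict:
    """Per-document occurrence counts of one n-gram feature, by period."""
    counts = {"proximal": [], "distal": []}
    for stream in streams:
        c = sum(1 for g in extract_ngrams(stream.tokens, n) if g == feature)
        counts[stream.period].append(c)
    return counts


def distinctiveness_threshold(
    feature: str,
    streams: Sequence[TokenStream],
    n: Optional[int] = None,
    p_max: float = 0.05,
    or_low: float = 0.66,
    or_high: float = 1.50,
) -> Optional[int]:
    """Smallest per-document count t at which "count >= t" is discriminative.

    The indicator is folded into the word-retention gates (two-sided exact
    p <= ``p_max`` and OR outside the indifference band).  Returns None when
    no threshold up to the maximum observed per-document count qualifies.
    """
    if n is None:
        n = len(feature.split())
    counts = _doc_counts(streams, feature, n)
    prox = np.asarray(counts["proximal"], dtype=np.int64)
    dist = np.asarray(counts["distal"], dtype=np.int64)
    max_count = int(max(prox.max(initial=0), dist.max(initial=0)))
    for t in range(1, max_count + 1):
        table = TwoByTwo(
            a=int((prox >= t).sum()),
            b=int((prox < t).sum()),
            c=int((dist >= t).sum()),
            d=int((dist < t).sum()),
        )
        orr = odds_ratio(table)
        if (orr < or_low or orr > or_high) and p_value(table) <= p_max:
            return t
    return None


def top_informative(
    model: NgramModel,
    streams: Sequence[TokenStream],
    k: int = 30,
    compute_t_star: bool = True,
) -> list[FeatureReport]:
    """Rank features by informativeness and build the top-k report.

    Informativeness is |log P(f|proximal) − log P(f|distal)|; ties break by
    total corpus frequency descending, then lexicographically.  If k exceeds
    the vocabulary, the whole vocabulary is returned (logged).
    """
    v = len(model.vocabulary)
    if k > v:
        logger.info("k=%d exceeds vocabulary size %d; returning all", k, v)
        k = v
    info = np.abs(
        model.log_likelihood["proximal"] - model.log_likelihood["distal"]
    )
    totals = sum(model.class_feature_counts.values())
    order = sorted(
        range(v), key=lambda i: (-info[i], -totals[i], model.vocabulary[i])
    )[:k]

    # document-presence tables and mean frequencies for the selected features
    selected = {model.vocabulary[i] for i in order}
    presence = {f: {"proximal": 0, "distal": 0} for f in selected}
    occurrences = {f: 0 for f in selected}
    n_docs_total = 0
    n_docs = {"proximal": 0, "distal": 0}
    for stream in streams:
        n_docs_total += 1
        n_docs[stream.period] += 1
        grams = extract_ngrams(stream.tokens, model.n)
        seen = set()
        for g in grams:
            if g in selected:
                occurrences[g] += 1
                seen.add(g)
        for g in seen:
            presence[g][stream.period] += 1

    reports = []
    for i in order:
        f = model.vocabulary[i]
        table = TwoByTwo(
            a=presence[f]["proximal"],
            b=n_docs["proximal"] - presence[f]["proximal"],
            c=presence[f]["distal"],
            d=n_docs["distal"] - presence[f]["distal"],
        )
        enriched = (
            "proximal"
            if model.log_likelihood["proximal"][i]
            > model.log_likelihood["distal"][i]
            else "distal"
        )
        reports.append(
            FeatureReport(
                feature=f,
                n=model.n,
                informativeness=float(info[i]),
                enriched_period=enriched,
                odds_ratio=odds_ratio(table),
                p_value=p_value(table),
                mean_freq_per_doc=occurrences[f] / n_docs_total,
                t_star=(
                    distinctiveness_threshold(f, streams, model.n)
                    if compute_t_star
                    else None
                ),
            )
        )
    return reports


def feature_report_frame(reports: Iterable[FeatureReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "n": r.n,
                "informativeness": r.informativeness,
                "enriched_period": r.enriched_period,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "mean_freq_per_doc": r.mean_freq_per_doc,
                "t_star": r.t_star,
            }
            for r in reports
        ]
    )
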