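"""Tokenisation, POS filtering and lemmatisation of clinical note text.

Two token-stream preparations feed the downstream analyses:

* **word mode** — nouns, pronouns and verbs are kept as lowercase lemmas;
  every other word class is replaced by its part-of-speech placeholder label
  (Universal POS tags, uppercase); punctuation is dropped.  This stream feeds
  the document-level word discrimination, where only content words matter.
* **n-gram mode** — every word is replaced by its lemma and nothing is
  substituted, so function words ("to", "of", "the") and punctuation survive;
  hyphenated compounds ("self-harm") lemmatise to their space-separated parts
  so that the compound surfaces as a bigram.  This stream feeds the
  multinomial Naive Bayes n-gram analysis.

Tagging is pluggable.  The bundled :class:`FallbackTagger` is a closed
rule/lexicon tagger — deterministic, dependency-free, and covering the
synthetic vocabulary plus common English function words and inflections — so
the whole pipeline runs hermetically.  A statistical tagger (spaCy) can be
plugged in for real clinical text via :func:`get_tagger`\\ ("external").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "UPOS_TAGS",
    "TokenStream",
    "FallbackTagger",
    "get_tagger",
    "tokenize",
    "prepare_for_word_analysis",
    "prepare_for_ngram_analysis",
]

#: the Universal POS tag inventory — the closed placeholder label set
UPOS_TAGS = frozenset(
    "ADJ ADP ADV AUX CCONJ DET INTJ NOUN NUM PART PRON PROPN PUNCT SCONJ SYM VERB X".split()
)

#: word classes whose lemmas are retained (not placeholder-substituted)
CONTENT_TAGS = frozenset({"NOUN", "PROPN", "PRON", "VERB"})

_PUNCT_CHARS = ".,;:!?()\"'"


@dataclass
class TokenStream:
    """An ordered, prepared token sequence for one document."""

    doc_id: str
    tokens: list[str]
    period: Optional[str] = None
    meta: dict = field(default_factory=dict)


def _verb(lemma: str, *forms: str) -> dict[str, tuple[str, str]]:
    return {f: ("VERB", lemma) for f in (lemma, *forms)}


def _build_lexicon() -> dict[str, tuple[str, str]]:
    lex: dict[str, tuple[str, str]] = {}

    # pronouns (incl. possessives and the expletive "there")
    for w in (
        "i you he she it we they me him her us them himself herself my your "
        "his its our their hers mine yours theirs there who".split()
    ):
        lex[w] = ("PRON", w)
    # determiners
    for w in "the a an this that these those no some any each every".split():
        lex[w] = ("DET", w)
    lex["that"] = ("SCONJ", "that")  # context-free choice: complementiser reading
    # adpositions
    for w in "of in on at with by for from about into over under after before during".split():
        lex[w] = ("ADP", w)
    # particles
    lex["not"] = ("PART", "not")
    lex["to"] = ("PART", "to")
    # conjunctions
    for w in "and but or".split():
        lex[w] = ("CCONJ", w)
    for w in "if because while when as since".split():
        lex[w] = ("SCONJ", w)
    # auxiliaries / modals
    for w in "will would can could shall should may might must".split():
        lex[w] = ("AUX", w)
    # verbs with irregular or common inflections
    lex.update(_verb("be", "am", "is", "are", "was", "were", "been", "being"))
    lex.update(_verb("have", "has", "had", "having"))
    lex.update(_verb("do", "does", "did", "doing", "done"))
    lex.update(_verb("say", "says", "said", "saying"))
    lex.update(_verb("state", "states", "stated", "stating"))
    lex.update(_verb("report", "reports", "reported", "reporting"))
    lex.update(_verb("feel", "feels", "felt", "feeling"))
    lex.update(_verb("want", "wants", "wanted", "wanting"))
    lex.update(_verb("go", "goes", "went", "gone", "going"))
    lex.update(_verb("see", "sees", "saw", "seen", "seeing"))
    lex.update(_verb("take", "takes", "took", "taken", "taking"))
    lex.update(_verb("deny", "denies", "denied", "denying"))
    lex.update(_verb("attend", "attends", "attended", "attending"))
    lex.update(_verb("improve", "improves", "improved", "improving"))
    lex.update(_verb("present", "presents", "presented", "presenting"))
    lex.update(_verb("discuss", "discusses", "discussed", "discussing"))
    lex.update(_verb("sleep", "sleeps", "slept", "sleeping"))
    lex.update(_verb("express", "expresses", "expressed", "expressing"))
    # nouns
    for w in (
        "patient ward overdose medication plan risk harm family mood staff "
        "home hospital nurse doctor team review assessment appointment "
        "section leave night day week care ligature alcohol drug dose "
        "tablet paracetamol crisis thought ideation voice contact "
        "meal activity".split()
    ):
        lex[w] = ("NOUN", w)
    # hyphenated compound: single token, two-word lemma exposed in n-gram mode
    lex["self-harm"] = ("NOUN", "self-harm")
    # adjectives / adverbs
    for w in "suicidal low good safe mental unwell happy anxious".split():
        lex[w] = ("ADJ", w)
    for w in "very today currently again now here still".split():
        lex[w] = ("ADV", w)
    return lex


_LEXICON = _build_lexicon()

#: suffix-stripping rules tried, in order, on out-of-lexicon tokens
_SUFFIX_RULES = ("'s", "es", "s", "ed", "ing")


class FallbackTagger:
    """Deterministic closed-lexicon tagger with light suffix stripping.

    Maps a lowercase token to a ``(UPOS tag, lemma)`` pair.  Out-of-lexicon
    tokens fall back to ``("NOUN", token)`` (identity lemma), logged once per
    token, so the pipeline never fails on unseen vocabulary.
    """

    def __init__(self) -> None:
        self.lexicon = dict(_LEXICON)
        self._warned: set[str] = set()

    def __call__(self, token: str) -> tuple[str, str]:
        if not token:
            raise ValueError("empty token")
        if all(c in _PUNCT_CHARS for c in token):
            return ("PUNCT", token)
        if token.replace(".", "").replace(",", "").isdigit():
            return ("NUM", token)
        hit = self.lexicon.get(token)
        if hit is not None:
            return hit
        for suffix in _SUFFIX_RULES:
            if token.endswith(suffix) and len(token) > len(suffix) + 1:
                stem = token[: -len(suffix)]
                hit = self.lexicon.get(stem)
                if hit is not None:
                    return hit
        if token not in self._warned:
            self._warned.add(token)
            logger.debug("token %r not in lexicon; NOUN/identity fallback", token)
        return ("NOUN", token)


def get_tagger(name: str = "fallback") -> Callable[[str], tuple[str, str]]:
    """Return a tagger by name: ``fallback`` (bundled) or ``external`` (spaCy).

    The external tagger requires spaCy and an installed English model; it is
    wrapped to the same per-token interface.
    """
    if name == "fallback":
        return FallbackTagger()
    if name == "external":
        import spacy  # deferred: optional heavyweight dependency

        nlp = spacy.load("en_core_web_sm", disable=["parser", "ner"])

        def tag(token: str) -> tuple[str, str]:
            doc = nlp(token)
            if not doc:
                return ("NOUN", token)
            t = doc[0]
            return (t.pos_, t.lemma_.lower())

        return tag
    raise ValueError(f"unknown tagger: {name!r}")


def tokenize(text: str) -> list[str]:
    """Lowercase, whitespace-split, and peel punctuation into its own tokens.

    Hyphenated compounds are kept whole ("self-harm" stays one token).
    """
    tokens: list[str] = []
    for chunk in text.lower().split():
        lead: list[str] = []
        trail: list[str] = []
        while chunk and chunk[0] in _PUNCT_CHARS:
            lead.append(chunk[0])
            chunk = chunk[1:]
        while chunk and chunk[-1] in _PUNCT_CHARS:
            trail.append(chunk[-1])
            chunk = chunk[:-1]
        tokens.extend(lead)
        if chunk:
            tokens.append(chunk)
        tokens.extend(reversed(trail))
    return tokens


def prepare_for_word_analysis(
    text: str,
    tagger: Optional[Callable[[str], tuple[str, str]]] = None,
    doc_id: str = "",
    period: Optional[str] = None,
) -> TokenStream:
    """Prepare the content-word stream: lemmas for nouns/pronouns/verbs, POS
    placeholder labels for every other word class, punctuation dropped."""
    tagger = tagger or _default_tagger()
    out: list[str] = []
    for tok in tokenize(text):
        tag, lemma = tagger(tok)
        if tag == "PUNCT":
            continue
        out.append(lemma if tag in CONTENT_TAGS else tag)
    return TokenStream(doc_id=doc_id, tokens=out, period=period)


def prepare_for_ngram_analysis(
    text: str,
    tagger: Optional[Callable[[str], tuple[str, str]]] = None,
    doc_id: str = "",
    period: Optional[str] = None,
) -> TokenStream:
    """Prepare the n-gram stream: every word lemmatised, function words and
    punctuation retained, hyphenated lemmas split into their parts."""
    tagger = tagger or _default_tagger()
    out: list[str] = []
    for tok in tokenize(text):
        tag, lemma = tagger(tok)
        if tag == "PUNCT":
            out.append(tok)
        elif "-" in lemma:
            out.extend(p for p in lemma.split("-") if p)
        else:
            out.append(lemma)
    return TokenStream(doc_id=doc_id, tokens=out, period=period)


_SHARED_FALLBACK: Optional[FallbackTagger] = None


def _default_tagger() -> FallbackTagger:
    global _SHARED_FALLBACK
    if _SHARED_FALLBACK is None:
        _SHARED_FALLBACK = FallbackTagger()
    return _SHARED_FALLBACK
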