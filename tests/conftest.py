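"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from datetime import date
from functools import lru_cache

import pytest
from hypothesis import settings

from ehrwin.text_prep import FallbackTagger, TokenStream

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tagger():
    return FallbackTagger()


def make_stream(doc_id: str, tokens: list[str], period: str) -> TokenStream:
    return TokenStream(doc_id=doc_id, tokens=tokens, period=period)


@pytest.fixture
def toy_word_streams():
    """10 tiny word-mode streams with a hand-checkable incidence structure."""
    prox = [
        ["overdose", "risk"],
        ["overdose", "overdose", "patient"],
        ["risk", "patient"],
        ["overdose"],
        ["patient"],
    ]
    dist = [
        ["plan", "care"],
        ["plan", "patient"],
        ["care"],
        ["patient", "plan"],
        ["overdose", "plan"],
    ]
    return [
        make_stream(f"p{i}", toks, "proximal") for i, toks in enumerate(prox)
    ] + [make_stream(f"d{i}", toks, "distal") for i, toks in enumerate(dist)]


# ---------------------------------------------------------------------------
# independent oracles (never call package code)


@lru_cache(maxsize=None)
def _hypergeom_weights(r1: int, r2: int, c1: int) -> tuple[range, list[int]]:
    """Integer table weights C(r1,a)*C(r2,c1-a) over the support of a."""
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = range(lo, hi + 1)
    return support, [math.comb(r1, a) * math.comb(r2, c1 - a) for a in support]


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Exact integer weights; sums the probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's.
    """
    r1, r2, c1 = a + b, c + d, a + c
    support, weights = _hypergeom_weights(r1, r2, c1)
    obs = weights[a - support.start]
    total = sum(weights)
    return sum(w for w in weights if w <= obs) / total


def window_label_oracle(
    doc_date: date,
    suicide_admissions: list[tuple[date, date]],
) -> tuple[str | None, int | None]:
    """Literal per-document re-check of both window rules.

    ``suicide_admissions`` is a date-sorted list of (admit, discharge).
    Returns (period or None, index of the anchoring admission).
    """
    for k, (admit, _) in enumerate(suicide_admissions):
        off = (doc_date - admit).days
        if -31 <= off <= -1:
            return "proximal", k
    for k, (admit, _) in enumerate(suicide_admissions):
        off = (doc_date - admit).days
        if -365 <= off <= -300:
            if k == 0:
                return "distal", k
            prev_discharge = suicide_admissions[k - 1][1]
            if (doc_date - prev_discharge).days >= 300:
                return "distal", k
    return None, None
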