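"""Document-level word discrimination between proximal and distal periods.

Each word is scored on a presence/absence 2x2 table over documents:

====================  ==================  ================
                      contains word       lacks word
====================  ==================  ================
proximal documents    a                   b
distal documents      c                   d
====================  ==================  ================

The odds ratio ``(a*d)/(b*c)`` measures how much more (OR > 1) or less
(OR < 1) likely a proximal document is to use the word at least once; the
Haldane-Anscombe correction (+0.5 on every cell) is applied when any cell is
zero.  Significance uses the two-sided Fisher exact test by default (exact at
the small per-word counts typical here; a chi-square variant with continuity
correction is available for comparison).  Words are retained for downstream
categorisation when ``p <= p_max`` and the OR falls outside the
``(or_low, or_high)`` indifference band — defaults 0.05 and (0.66, 1.50).
No multiple-testing correction is applied by default; Benjamini-Hochberg can
be switched on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .text_prep import UPOS_TAGS, TokenStream

logger = logging.getLogger(__name__)

__all__ = [
    "TwoByTwo",
    "WordStat",
    "doc_term_incidence",
    "odds_ratio",
    "p_value",
    "compute_word_stats",
    "retain_words",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Document incidence counts: (a, b) proximal with/without, (c, d) distal."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n_proximal(self) -> int:
        return self.a + self.b

    @property
    def n_distal(self) -> int:
        return self.c + self.d


@dataclass
class WordStat:
    word: str
    table: TwoByTwo
    odds_ratio: float
    p_value: float
    retained: bool = False


def doc_term_incidence(streams: Iterable[TokenStream]) -> dict[str, TwoByTwo]:
    """Per-word document presence counts across the two periods.

    Streams must be prepared in word-analysis mode and carry a ``period`` of
    ``proximal`` or ``distal``.  Presence is binary per document; POS
    placeholder labels (uppercase Universal tags) are not words and are
    excluded from the inventory.  Raises ``ValueError`` if either period has
    no documents.
    """
    n_docs = {"proximal": 0, "distal": 0}
    present: dict[str, dict[str, int]] = {}
    for stream in streams:
        if stream.period not in n_docs:
            raise ValueError(f"stream {stream.doc_id!r} has period {stream.period!r}")
        n_docs[stream.period] += 1
        for word in set(stream.tokens):
            if word in UPOS_TAGS:
                continue
            present.setdefault(word, {"proximal": 0, "distal": 0})[stream.period] += 1
    if n_docs["proximal"] == 0 or n_docs["distal"] == 0:
        raise ValueError(f"a period has zero documents: {n_docs}")
    return {
        w: TwoByTwo(
            a=cnt["proximal"],
            b=n_docs["proximal"] - cnt["proximal"],
            c=cnt["distal"],
            d=n_docs["distal"] - cnt["distal"],
        )
        for w, cnt in present.items()
    }


def odds_ratio(table: TwoByTwo) -> float:
    """Cross-product ratio; +0.5 on every cell when any cell is zero."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.n_proximal == 0 and table.n_distal == 0:
        raise ValueError("both periods empty")
    if min(a, b, c, d) == 0:
        logger.debug("zero cell in %s: Haldane-Anscombe +0.5 applied", table)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def p_value(table: TwoByTwo, method: str = "fisher") -> float:
    """Two-sided association p-value for the 2x2 table.

    ``fisher`` (default) sums hypergeometric probabilities of all tables with
    the observed margins that are no more probable than the observed one —
    computed in log space, overflow-safe for large counts.  ``chi2`` is the
    chi-square test with Yates continuity correction.
    """
    obs = [[table.a, table.b], [table.c, table.d]]
    if method == "fisher":
        return float(stats.fisher_exact(obs, alternative="two-sided").pvalue)
    if method == "chi2":
        if table.a + table.c == 0 or table.b + table.d == 0:
            return 1.0  # degenerate column margin: no association testable
        res = stats.chi2_contingency(obs, correction=True)
        return float(res.pvalue)
    raise ValueError(f"unknown method: {method!r}")


def compute_word_stats(
    streams: Iterable[TokenStream],
    method: str = "fisher",
    exclude: Optional[Iterable[str]] = None,
    fdr: bool = False,
) -> list[WordStat]:
    """Incidence, OR and p-value for every word in the corpus.

    ``exclude`` is a manual curation list (abbreviations, dates, locations,
    ambiguous words) removed from the inventory before testing.  With
    ``fdr=True``, p-values are Benjamini-Hochberg adjusted before the
    retention filter (off by default: the raw-p filter is the primary
    procedure).
    """
    excluded = {w.strip().lower() for w in exclude} if exclude else set()
    tables = doc_term_incidence(streams)
    stats_list = [
        WordStat(w, t, odds_ratio(t), p_value(t, method=method))
        for w, t in sorted(tables.items())
        if w not in excluded
    ]
    if fdr and stats_list:
        adjusted = _benjamini_hochberg([s.p_value for s in stats_list])
        for s, q in zip(stats_list, adjusted):
            s.p_value = q
    return stats_list


def _benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    out = [0.0] * m
    running = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, pvals[i] * m / rank)
        out[i] = running
    return out


def retain_words(
    stats_list: Iterable[WordStat],
    p_max: float = 0.05,
    or_low: float = 0.66,
    or_high: float = 1.50,
) -> list[WordStat]:
    """Apply the discrimination filter and sort for curation export.

    A word is retained when ``p <= p_max`` (inclusive) and its odds ratio is
    strictly below ``or_low`` or strictly above ``or_high``.  Retained words
    are returned sorted by |log OR| descending (strongest discriminators
    first).
    """
    retained = []
    for s in stats_list:
        s.retained = s.p_value <= p_max and (
            s.odds_ratio < or_low or s.odds_ratio > or_high
        )
        if s.retained:
            retained.append(s)
    retained.sort(key=lambda s: (-abs(math.log(s.odds_ratio)), s.word))
    return retained


def word_stats_frame(stats_list: Iterable[WordStat]) -> pd.DataFrame:
    """Flatten WordStats to the word-stats CSV schema."""
    return pd.DataFrame(
        [
            {
                "word": s.word,
                "a": s.table.a,
                "b": s.table.b,
                "c": s.table.c,
                "d": s.table.d,
                "odds_ratio": s.odds_ratio,
                "p_value": s.p_value,
                "retained": s.retained,
            }
            for s in stats_list
        ]
    )
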