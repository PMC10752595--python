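"""Category-level exposure odds ratios and inter-annotator agreement.

Discriminative words are grouped by clinicians into semantic categories
(e.g. care-plan language, overdose/medication terms).  A document is
*exposed* to a category when it contains at least one member word; exposure
counts form the same proximal/distal 2x2 table used for single words, and
the category odds ratio is computed identically.

When a second annotator independently assigns the same word list to the same
category inventory, agreement is summarised by a confusion matrix, Cohen's
kappa, and per-category precision/recall/F1 with the first annotator as the
reference: recall(c) is the share of the reference's category-c words the
second annotator also put in c, precision(c) the share of the second
annotator's category-c words that the reference put there, and F1 their
harmonic mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .text_prep import TokenStream
from .word_discrimination import TwoByTwo, odds_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "WordCategory",
    "CategoryStat",
    "category_exposure",
    "confusion_matrix",
    "per_category_prf",
    "cohens_kappa",
    "f1_score",
]


@dataclass(frozen=True)
class WordCategory:
    category_id: str
    description: str
    words: frozenset[str]


@dataclass
class CategoryStat:
    category_id: str
    table: TwoByTwo
    odds_ratio: float
    zero_exposure: bool = False


def category_exposure(
    streams: Iterable[TokenStream],
    categories: Iterable[WordCategory],
) -> list[CategoryStat]:
    """Per-category exposed-document 2x2 tables and odds ratios.

    A document is exposed iff it contains >= 1 member lemma of the category.
    Categories with no exposure anywhere still get an OR (zero-cell
    correction applies) but are flagged ``zero_exposure``.
    """
    cats = list(categories)
    if not cats:
        raise ValueError("no categories given")
    n_docs = {"proximal": 0, "distal": 0}
    exposed = {c.category_id: {"proximal": 0, "distal": 0} for c in cats}
    for stream in streams:
        if stream.period not in n_docs:
            raise ValueError(f"stream {stream.doc_id!r} has period {stream.period!r}")
        n_docs[stream.period] += 1
        toks = set(stream.tokens)
        for c in cats:
            if toks & c.words:
                exposed[c.category_id][stream.period] += 1
    out = []
    for c in cats:
        cnt = exposed[c.category_id]
        table = TwoByTwo(
            a=cnt["proximal"],
            b=n_docs["proximal"] - cnt["proximal"],
            c=cnt["distal"],
            d=n_docs["distal"] - cnt["distal"],
        )
        zero = cnt["proximal"] + cnt["distal"] == 0
        if zero:
            logger.warning("category %s has no exposed documents", c.category_id)
        out.append(CategoryStat(c.category_id, table, odds_ratio(table), zero))
    return out


def _check_same_words(a: Mapping[str, str], b: Mapping[str, str]) -> None:
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))[:5]
        only_b = sorted(set(b) - set(a))[:5]
        raise ValueError(
            f"annotators labelled different word lists (e.g. A-only {only_a}, "
            f"B-only {only_b})"
        )
    if not a:
        raise ValueError("empty assignment")


def confusion_matrix(
    assignments_a: Mapping[str, str], assignments_b: Mapping[str, str]
) -> pd.DataFrame:
    """Cross-tabulation of category assignments, A on rows, B on columns.

    Rows and columns span the union of categories used by either annotator,
    so row sums equal A's category sizes and column sums B's.
    """
    _check_same_words(assignments_a, assignments_b)
    cats = sorted(set(assignments_a.values()) | set(assignments_b.values()))
    mat = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    for word, cat_a in assignments_a.items():
        mat.loc[cat_a, assignments_b[word]] += 1
    return mat


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision == 0 and recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def per_category_prf(
    assignments_a: Mapping[str, str], assignments_b: Mapping[str, str]
) -> pd.DataFrame:
    """Per-category precision, recall and F1, with annotator A as reference.

    recall(c) = |A's c ∩ B's c| / |A's c|; precision(c) = same numerator /
    |B's c| (0 when B used c for no word).  Directions swap under
    A/B exchange: precision(A→B) = recall(B→A).
    """
    mat = confusion_matrix(assignments_a, assignments_b)
    rows = []
    for c in mat.index:
        agree = int(mat.loc[c, c])
        size_a = int(mat.loc[c].sum())
        size_b = int(mat[c].sum())
        recall = agree / size_a if size_a else 0.0
        precision = agree / size_b if size_b else 0.0
        rows.append(
            {
                "category": c,
                "n_reference": size_a,
                "precision": precision,
                "recall": recall,
                "f1": f1_score(precision, recall),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def cohens_kappa(
    assignments_a: Mapping[str, str], assignments_b: Mapping[str, str]
) -> float:
    """Chance-corrected agreement between the two annotators.

    kappa = (p_o − p_e) / (1 − p_e) with observed agreement p_o the fraction
    of identically categorised words and expected agreement p_e the product
    of the annotators' marginal category shares summed over categories.  In
    the degenerate case p_e = 1 (both annotators use a single common
    category), kappa is defined as 1 when p_o = 1 and 0 otherwise.
    """
    mat = confusion_matrix(assignments_a, assignments_b)
    n = mat.values.sum()
    p_o = sum(mat.loc[c, c] for c in mat.index) / n
    marg_a = mat.sum(axis=1) / n
    marg_b = mat.sum(axis=0) / n
    p_e = float((marg_a * marg_b).sum())
    if p_e >= 1.0:
        logger.warning("degenerate single-category agreement (p_e = 1)")
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def read_category_files(paths) -> list[WordCategory]:
    """Read plain-text category files: first line ``id<TAB>description``,
    then one member word per line."""
    cats = []
    for path in paths:
        with open(path) as fh:
            header = fh.readline().strip()
            cat_id, _, desc = header.partition("\t")
            words = frozenset(
                line.strip().lower() for line in fh if line.strip()
            )
        cats.append(WordCategory(cat_id, desc, words))
    ids = [c.category_id for c in cats]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate category ids")
    return cats


def read_assignments_csv(path) -> dict[str, str]:
    """Read an annotator assignment CSV with columns word, category_id."""
    df = pd.read_csv(path, dtype=str)
    dup = df["word"].duplicated()
    if dup.any():
        raise ValueError(
            f"word assigned to more than one category: {df.loc[dup, 'word'].tolist()}"
        )
    return dict(zip(df["word"].str.lower(), df["category_id"]))
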