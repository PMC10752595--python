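"""Per-patient documentation rate and event-aligned monitoring trajectories.

The monitoring level of a patient at a reference date is the number of
documents written in the preceding ``W`` days divided by ``W`` — an average
documents-per-day rate.  The window is the closed day interval
``[reference − W, reference − 1]``: the reference day itself is excluded, so
30 documents in the 30 days before the reference date give
``MonitoringLevel_30 = 1.0``.

A patient counts as *under monitoring* at a date once at least one document
exists strictly before that date.  Cohort trajectories align every patient on
their first suicide attempt and report, for each day offset ``d < 0``, the
fraction of under-monitoring patients with at least ``min_docs`` documents in
the W-day window preceding ``attempt_date + d``.  Patients with no
pre-attempt documents never enter numerator or denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonitoringPoint",
    "monitoring_level",
    "under_monitoring",
    "aligned_trajectory",
    "percentage",
]


@dataclass(frozen=True)
class MonitoringPoint:
    patient_id: str
    reference_date: date
    window_days: int
    n_docs_in_window: int

    @property
    def level(self) -> float:
        """Documents per day over the window."""
        return self.n_docs_in_window / self.window_days


def _dates(doc_dates: Iterable) -> list[date]:
    return [d if isinstance(d, date) else pd.Timestamp(d).date() for d in doc_dates]


def monitoring_level(
    doc_dates: Iterable,
    reference_date: date,
    window_days: int = 30,
    patient_id: str = "",
) -> MonitoringPoint:
    """Documentation rate over the ``window_days`` days before ``reference_date``.

    Counts documents dated in the closed interval
    ``[reference_date − window_days, reference_date − 1]`` and normalises by
    the window size.  Raises ``ValueError`` for ``window_days < 1``.
    """
    if window_days < 1:
        raise ValueError(f"window_days must be >= 1, got {window_days}")
    lo = reference_date - timedelta(days=window_days)
    hi = reference_date - timedelta(days=1)
    n = sum(1 for d in _dates(doc_dates) if lo <= d <= hi)
    return MonitoringPoint(patient_id, reference_date, window_days, n)


def under_monitoring(doc_dates: Iterable, reference_date: date) -> bool:
    """True iff at least one document exists strictly before ``reference_date``."""
    return any(d < reference_date for d in _dates(doc_dates))


def aligned_trajectory(
    documents: pd.DataFrame,
    attempt_dates: Mapping[str, date],
    offsets: Sequence[int] = range(-365, 0),
    window_days: int = 30,
    min_docs: int = 1,
) -> pd.DataFrame:
    """Cohort monitoring trajectory aligned on the first suicide attempt.

    Parameters
    ----------
    documents
        DataFrame with columns ``patient_id`` and ``date``.
    attempt_dates
        First-attempt date per patient; patients absent from the map are
        ignored, as are patients with no document before their attempt.
    offsets
        Negative day offsets relative to the attempt at which to evaluate.
    min_docs
        Numerator threshold: a patient counts as monitored at an offset when
        at least this many documents fall in the preceding window.  The
        default 1 follows the "at least one document in the past 30 days"
        reading; pass 2 for the "more than one document" variant.

    Returns
    -------
    DataFrame with one row per offset: ``offset, numerator, denominator,
    fraction`` (fraction is NaN where the denominator is zero).
    """
    offs = np.asarray(list(offsets), dtype=np.int64)
    if offs.size == 0:
        raise ValueError("no offsets given")
    if (offs >= 0).any():
        raise ValueError("offsets must be negative (days before the attempt)")
    if not attempt_dates:
        raise ValueError("empty cohort: no attempt dates")

    numer = np.zeros(offs.size, dtype=np.int64)
    denom = np.zeros(offs.size, dtype=np.int64)

    doc_dates = pd.to_datetime(documents["date"])
    by_patient = pd.Series(doc_dates.values).groupby(
        documents["patient_id"].values
    )
    doc_map = {pid: np.sort(vals.values) for pid, vals in by_patient}

    for pid, attempt in attempt_dates.items():
        dates = doc_map.get(pid)
        if dates is None or dates.size == 0:
            continue
        # day offsets of this patient's documents relative to the attempt
        rel = (dates - np.datetime64(pd.Timestamp(attempt), "ns")) // np.timedelta64(
            1, "D"
        )
        rel = np.sort(rel.astype(np.int64))
        if rel[0] >= 0:  # no pre-attempt documents: excluded entirely
            continue
        # docs strictly before offset d  /  docs in [d - W, d - 1]
        n_before = np.searchsorted(rel, offs, side="left")
        n_window = n_before - np.searchsorted(rel, offs - window_days, side="left")
        in_denom = n_before >= 1
        denom += in_denom
        numer += in_denom & (n_window >= min_docs)

    frac = np.divide(
        numer, denom, out=np.full(offs.size, np.nan), where=denom > 0
    )
    return pd.DataFrame(
        {"offset": offs, "numerator": numer, "denominator": denom, "fraction": frac}
    )


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Share of ``numerator`` in ``denominator`` as a percentage, rounded."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, ndigits)
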