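"""Hospital episode consolidation and suicide-attempt cohort definition.

Hospital Episode Statistics (HES) records arrive as finished consultant
episodes: one row per period of responsibility of a single consultant, with a
start date, an end date and an ICD-10 diagnosis code.  A hospital *admission*
(a "spell") is the continuous in-hospital stay built by merging episodes whose
date ranges overlap or abut.  An admission is suicide-related when any of its
constituent episodes carries an ICD-10 code for intentional self-harm
(X60-X84), an event of undetermined intent (Y10-Y34), or their sequelae
(Y87.0 / Y87.2); downstream analyses pool these ranges.

All dates are day-resolution ``datetime.date`` values (HES has no
time-of-day).  Two episodes merge when the next one starts on or before the
day the previous one ends (gap of zero days); a one-day gap starts a new
admission.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Episode",
    "Admission",
    "is_suicide_code",
    "consolidate_episodes",
    "consolidate_all",
    "first_attempt_date",
    "read_episodes_csv",
    "write_admissions_csv",
]

#: lexical pattern for the ICD-10 codes accepted here: a letter, two digits,
#: and an optional dot-separated 1-2 digit extension (e.g. "X60", "X60.1").
_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]{1,2})?$")

#: 4-character sequelae codes counted as suicide-related on exact stem match.
_SEQUELAE_CODES = ("Y87.0", "Y87.2")


@dataclass(frozen=True)
class Episode:
    """One finished consultant episode."""

    patient_id: str
    epi_start: date
    epi_end: date
    icd10_code: str

    def __post_init__(self) -> None:
        if self.epi_end < self.epi_start:
            raise ValueError(
                f"episode for {self.patient_id}: epi_end {self.epi_end} "
                f"precedes epi_start {self.epi_start}"
            )


@dataclass(frozen=True)
class Admission:
    """A consolidated hospital spell.

    ``suicide_related`` is true when any constituent episode carries a
    suicide-related ICD-10 code.
    """

    patient_id: str
    admit_date: date
    discharge_date: date
    suicide_related: bool
    episode_indices: tuple[int, ...] = field(default_factory=tuple)


def is_suicide_code(code: str) -> bool:
    """Return True when ``code`` denotes a hospitalised suicide attempt.

    The suicide-related set is the three-character stems X60-X84 and Y10-Y34
    (4-character children of in-range stems, e.g. ``X60.1``, included), plus
    exactly Y87.0 and Y87.2.  Y87 itself and its other children are not
    suicide-related.

    Raises ``ValueError`` for strings that are not syntactically valid ICD-10
    codes.
    """
    code = code.strip().upper()
    if not _ICD10_RE.match(code):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    stem, letter, number = code[:3], code[0], int(code[1:3])
    if stem == "Y87":
        return code in _SEQUELAE_CODES
    if letter == "X":
        return 60 <= number <= 84
    if letter == "Y":
        return 10 <= number <= 34
    return False


def _as_episode(obj) -> Episode:
    if isinstance(obj, Episode):
        return obj
    # mapping / namedtuple-style row
    return Episode(
        patient_id=str(obj["patient_id"]),
        epi_start=_as_date(obj["epi_start"]),
        epi_end=_as_date(obj["epi_end"]),
        icd10_code=str(obj["icd10_code"]),
    )


def _as_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, pd.Timestamp):
        return value
    return pd.Timestamp(value).date()


def consolidate_episodes(episodes: Sequence) -> list[Admission]:
    """Merge one patient's episodes into admissions (spells).

    Episodes whose date ranges overlap or abut — the next start on or before
    the current end — form one admission spanning the earliest start to the
    latest end.  The admission is flagged suicide-related if any constituent
    episode's code is.

    Raises ``ValueError`` if episodes from more than one patient are passed.
    """
    eps = [_as_episode(e) for e in episodes]
    if not eps:
        return []
    patients = {e.patient_id for e in eps}
    if len(patients) > 1:
        raise ValueError(f"episodes from multiple patients: {sorted(patients)}")

    order = sorted(range(len(eps)), key=lambda i: (eps[i].epi_start, eps[i].epi_end))
    admissions: list[Admission] = []
    cur_idx = [order[0]]
    cur_start = eps[order[0]].epi_start
    cur_end = eps[order[0]].epi_end
    cur_suicide = is_suicide_code(eps[order[0]].icd10_code)
    pid = eps[0].patient_id

    for i in order[1:]:
        e = eps[i]
        if e.epi_start <= cur_end:  # overlap or abut: same spell
            cur_idx.append(i)
            cur_end = max(cur_end, e.epi_end)
            cur_suicide = cur_suicide or is_suicide_code(e.icd10_code)
        else:
            admissions.append(
                Admission(pid, cur_start, cur_end, cur_suicide, tuple(cur_idx))
            )
            cur_idx = [i]
            cur_start, cur_end = e.epi_start, e.epi_end
            cur_suicide = is_suicide_code(e.icd10_code)
    admissions.append(Admission(pid, cur_start, cur_end, cur_suicide, tuple(cur_idx)))
    return admissions


def consolidate_all(episodes: pd.DataFrame) -> pd.DataFrame:
    """Consolidate an episode table (all patients) into an admission table.

    Parameters
    ----------
    episodes
        DataFrame with columns ``patient_id, epi_start, epi_end, icd10_code``.

    Returns
    -------
    DataFrame with columns ``admission_id, patient_id, admit_date,
    discharge_date, suicide_related`` sorted by patient then admit date.
    """
    rows = []
    for pid, grp in episodes.groupby("patient_id", sort=True):
        adms = consolidate_episodes(list(grp.to_dict("records")))
        for k, adm in enumerate(adms):
            rows.append(
                {
                    "admission_id": f"{pid}-A{k}",
                    "patient_id": adm.patient_id,
                    "admit_date": adm.admit_date,
                    "discharge_date": adm.discharge_date,
                    "suicide_related": adm.suicide_related,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "admission_id",
            "patient_id",
            "admit_date",
            "discharge_date",
            "suicide_related",
        ],
    )


def first_attempt_date(
    admissions: Iterable,
    window_start: Optional[date] = None,
    window_end: Optional[date] = None,
) -> Optional[date]:
    """Admit date of a patient's earliest suicide-related admission.

    The admission anchor is the admit date (all pre-attempt windows count
    backwards from hospital arrival).  ``window_start``/``window_end`` bound
    the study window as a closed interval on the admit date.  Returns None
    when the patient has no qualifying suicide-related admission.
    """
    best: Optional[date] = None
    for adm in admissions:
        if isinstance(adm, Admission):
            suicide, admit = adm.suicide_related, adm.admit_date
        else:
            suicide, admit = bool(adm["suicide_related"]), _as_date(adm["admit_date"])
        if not suicide:
            continue
        if window_start is not None and admit < window_start:
            continue
        if window_end is not None and admit > window_end:
            continue
        if best is None or admit < best:
            best = admit
    return best


def read_episodes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "icd10_code": str})
    for col in ("epi_start", "epi_end"):
        df[col] = pd.to_datetime(df[col]).dt.date
    return df


def write_admissions_csv(admissions: pd.DataFrame, path) -> None:
    admissions.to_csv(path, index=False)
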