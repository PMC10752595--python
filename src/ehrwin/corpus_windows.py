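"""Proximal/distal window assignment and the document length filter.

Documents are compared across two risk periods anchored on suicide-related
hospital admissions:

* **proximal** — written between 31 and 1 days before any suicide-related
  admission (closed day interval ``[admit − 31, admit − 1]``; the admission
  day itself never qualifies);
* **distal** — written between 365 and 300 days before a suicide-related
  admission (``[admit − 365, admit − 300]``), and, for admissions after the
  first, only when the document also falls at least 300 days after the
  previous suicide-related admission's discharge (so a "distal" note is never
  shortly after an earlier attempt).

A document qualifying for several admissions is kept once, anchored to the
earliest qualifying admission.  A document qualifying for both periods is
labelled proximal (the label that drives the risk-detection use case) and the
conflict is logged.  Only documents longer than ``min_chars`` characters of
raw text (whitespace included) are retained — short administrative stubs
carry no analysable language.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PROXIMAL_WINDOW",
    "DISTAL_WINDOW",
    "LabeledCorpus",
    "proximal_documents",
    "distal_documents",
    "build_labeled_corpus",
    "write_labeled_corpus_jsonl",
    "read_labeled_corpus_jsonl",
]

#: closed day-offset windows relative to the admit date
PROXIMAL_WINDOW = (-31, -1)
DISTAL_WINDOW = (-365, -300)

#: minimum days from a previous suicide admission's discharge to a distal doc
DISTAL_CLEARANCE_DAYS = 300


@dataclass
class LabeledCorpus:
    """Documents labelled proximal/distal with per-period summary counts."""

    documents: pd.DataFrame  # doc_id, patient_id, date, text, period, anchor_admission_id
    n_docs: dict = field(default_factory=dict)  # period -> document count
    n_patients: dict = field(default_factory=dict)  # period -> distinct patients
    n_patients_both: int = 0  # patients contributing to both periods


def _to_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, pd.Timestamp):
        return value
    return pd.Timestamp(value).date()


def _suicide_admissions(admissions: pd.DataFrame) -> pd.DataFrame:
    adm = admissions[admissions["suicide_related"].astype(bool)].copy()
    adm["admit_date"] = adm["admit_date"].map(_to_date)
    adm["discharge_date"] = adm["discharge_date"].map(_to_date)
    return adm.sort_values(["patient_id", "admit_date"])


def _assign(
    documents: pd.DataFrame, admissions: pd.DataFrame, period: str
) -> pd.DataFrame:
    """Documents qualifying for ``period``, anchored to the earliest
    qualifying admission; one row per document."""
    sui = _suicide_admissions(admissions)
    lo_off, hi_off = PROXIMAL_WINDOW if period == "proximal" else DISTAL_WINDOW
    out_rows = []
    adm_by_patient = dict(iter(sui.groupby("patient_id")))
    for pid, docs in documents.groupby("patient_id"):
        adms = adm_by_patient.get(pid)
        if adms is None:
            continue
        adm_records = adms.to_dict("records")
        for doc in docs.to_dict("records"):
            d = _to_date(doc["date"])
            anchor = None
            for k, adm in enumerate(adm_records):
                admit = adm["admit_date"]
                lo = admit + timedelta(days=lo_off)
                hi = admit + timedelta(days=hi_off)
                if not (lo <= d <= hi):
                    continue
                if period == "distal" and k > 0:
                    prev_discharge = adm_records[k - 1]["discharge_date"]
                    if (d - prev_discharge).days < DISTAL_CLEARANCE_DAYS:
                        continue
                anchor = adm["admission_id"]
                break  # admissions sorted: first hit is the earliest
            if anchor is not None:
                row = dict(doc)
                row["date"] = d
                row["period"] = period
                row["anchor_admission_id"] = anchor
                out_rows.append(row)
    cols = ["doc_id", "patient_id", "date", "text", "period", "anchor_admission_id"]
    return pd.DataFrame(out_rows, columns=cols)


def proximal_documents(
    documents: pd.DataFrame, admissions: pd.DataFrame
) -> pd.DataFrame:
    """Documents in the 31-to-1-day window before any suicide admission."""
    return _assign(documents, admissions, "proximal")


def distal_documents(
    documents: pd.DataFrame, admissions: pd.DataFrame
) -> pd.DataFrame:
    """Documents in the 365-to-300-day window before a suicide admission,
    respecting the 300-day clearance from the previous suicide discharge."""
    return _assign(documents, admissions, "distal")


def build_labeled_corpus(
    documents: pd.DataFrame,
    admissions: pd.DataFrame,
    min_chars: int = 100,
) -> LabeledCorpus:
    """Label documents proximal/distal and apply the length filter.

    Documents must carry globally unique ``doc_id`` values.  Documents whose
    raw text is not strictly longer than ``min_chars`` characters are
    dropped.  A document matching both windows is assigned proximal and the
    conflict logged.
    """
    if documents["doc_id"].duplicated().any():
        raise ValueError("doc_id values are not unique across patients")

    docs = documents[documents["text"].str.len() > min_chars]
    prox = proximal_documents(docs, admissions)
    dist = distal_documents(docs, admissions)

    dual = set(prox["doc_id"]) & set(dist["doc_id"])
    if dual:
        logger.info(
            "%d documents qualified for both periods; assigned proximal", len(dual)
        )
        dist = dist[~dist["doc_id"].isin(dual)]

    labeled = pd.concat([prox, dist], ignore_index=True)
    n_docs = labeled["period"].value_counts().to_dict()
    patients = {
        p: set(labeled.loc[labeled["period"] == p, "patient_id"])
        for p in ("proximal", "distal")
    }
    return LabeledCorpus(
        documents=labeled,
        n_docs={p: int(n_docs.get(p, 0)) for p in ("proximal", "distal")},
        n_patients={p: len(v) for p, v in patients.items()},
        n_patients_both=len(patients["proximal"] & patients["distal"]),
    )


def write_labeled_corpus_jsonl(corpus: LabeledCorpus, path) -> None:
    with open(path, "w") as fh:
        for row in corpus.documents.to_dict("records"):
            row = dict(row)
            row["date"] = row["date"].isoformat()
            fh.write(json.dumps(row) + "\n")


def read_labeled_corpus_jsonl(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    df = pd.DataFrame(rows)
    if not df.empty:
        df["date"] = df["date"].map(_to_date)
    return df
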