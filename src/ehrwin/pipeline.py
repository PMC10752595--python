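"""End-to-end orchestration: simulate/load -> cohort -> monitoring ->
windows -> text preparation -> word, category and n-gram analyses.

Every stage's output is persisted to the run directory (auditability over
disk economy: the derivation counts at each filter are themselves a result),
and a run manifest records the configuration hash and seed so a bundle can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from datetime import date
from typing import Optional

import pandas as pd
import yaml

from . import (
    category_analysis,
    cohort,
    corpus_windows,
    monitoring,
    ngram_nb,
    synthetic_ehr,
    text_prep,
    word_discrimination,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_all", "load_config"]


@dataclass
class PipelineConfig:
    """Run configuration; every default is the analysis default."""

    # input: either paths to existing tables, or a simulation
    episodes_csv: Optional[str] = None
    documents_jsonl: Optional[str] = None
    simulate: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    # study window (closed) for locating first attempts
    window_start: Optional[date] = None
    window_end: Optional[date] = None
    # monitoring
    monitor_window_days: int = 30
    monitor_min_docs: int = 1
    trajectory_offsets: tuple[int, int] = (-365, -1)
    # corpus windows
    min_chars: int = 100
    # word discrimination
    p_max: float = 0.05
    or_low: float = 0.66
    or_high: float = 1.50
    test_method: str = "fisher"
    # n-gram NB
    ngram_orders: tuple[int, ...] = (1, 2, 3)
    top_k: int = 30
    alpha: float = 1.0
    seed: int = 0
    out_dir: str = "ehrwin_run"

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration with validation."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("window_start", "window_end"):
        if raw.get(key) is not None and not isinstance(raw[key], date):
            raw[key] = date.fromisoformat(str(raw[key]))
    for key in ("trajectory_offsets", "ngram_orders"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    if not 0 < cfg.p_max < 1:
        raise ValueError("p_max must be in (0, 1)")
    if not 0 < cfg.or_low < cfg.or_high:
        raise ValueError("need 0 < or_low < or_high")
    return cfg


@dataclass
class ReportBundle:
    """Paths and in-memory frames of every artefact of one run."""

    out_dir: str
    admissions: pd.DataFrame
    trajectory: pd.DataFrame
    corpus_summary: dict
    word_stats: pd.DataFrame
    category_stats: Optional[pd.DataFrame]
    feature_reports: dict[int, pd.DataFrame]
    manifest: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _load_documents_jsonl(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    df = pd.DataFrame(rows)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def run_all(config: PipelineConfig) -> ReportBundle:
    """Execute the whole pipeline; every stage's outputs are persisted."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": {},
    }

    # --- input stage -----------------------------------------------------
    if config.simulate:
        sim_kwargs = dict(config.simulation)
        for key in ("study_start", "study_end"):
            if key in sim_kwargs and not isinstance(sim_kwargs[key], date):
                sim_kwargs[key] = date.fromisoformat(str(sim_kwargs[key]))
        sim_cfg = synthetic_ehr.SimulationConfig(seed=config.seed, **sim_kwargs)
        episodes, documents, sim_manifest = synthetic_ehr.generate_cohort(sim_cfg)
        synthetic_ehr.write_outputs(out, episodes, documents, sim_manifest)
    else:
        if not (config.episodes_csv and config.documents_jsonl):
            raise StageError("input", "need episodes_csv and documents_jsonl")
        episodes = cohort.read_episodes_csv(config.episodes_csv)
        documents = _load_documents_jsonl(config.documents_jsonl)
    manifest["counts"]["episodes"] = len(episodes)
    manifest["counts"]["documents"] = len(documents)
    manifest["counts"]["patients"] = documents["patient_id"].nunique()

    # --- cohort ----------------------------------------------------------
    admissions = cohort.consolidate_all(episodes)
    admissions.to_csv(os.path.join(out, "admissions.csv"), index=False)
    attempts = {}
    for pid, grp in admissions.groupby("patient_id"):
        d = cohort.first_attempt_date(
            grp.to_dict("records"), config.window_start, config.window_end
        )
        if d is not None:
            attempts[pid] = d
    manifest["counts"]["admissions"] = len(admissions)
    manifest["counts"]["patients_with_attempt"] = len(attempts)
    if not attempts:
        manifest["status"] = "no suicide-related admissions"
        _write_manifest(out, manifest)
        raise StageError("cohort", "no suicide-related admissions in input")

    # --- monitoring ------------------------------------------------------
    lo, hi = config.trajectory_offsets
    trajectory = monitoring.aligned_trajectory(
        documents,
        attempts,
        offsets=range(lo, hi + 1),
        window_days=config.monitor_window_days,
        min_docs=config.monitor_min_docs,
    )
    trajectory.to_csv(os.path.join(out, "trajectory.csv"), index=False)

    # --- corpus windows --------------------------------------------------
    corpus = corpus_windows.build_labeled_corpus(
        documents, admissions, min_chars=config.min_chars
    )
    corpus_windows.write_labeled_corpus_jsonl(
        corpus, os.path.join(out, "labeled_corpus.jsonl")
    )
    summary = {
        "n_docs": corpus.n_docs,
        "n_patients": corpus.n_patients,
        "n_patients_both": corpus.n_patients_both,
    }
    manifest["counts"]["labeled_corpus"] = summary
    if corpus.documents.empty or corpus.documents["period"].nunique() < 2:
        manifest["status"] = "corpus lacks one of the periods; text stages skipped"
        _write_manifest(out, manifest)
        raise StageError("corpus_windows", "need documents in both periods")

    # --- text preparation ------------------------------------------------
    tagger = text_prep.get_tagger("fallback")
    word_streams = [
        text_prep.prepare_for_word_analysis(
            r["text"], tagger, doc_id=r["doc_id"], period=r["period"]
        )
        for r in corpus.documents.to_dict("records")
    ]
    ngram_streams = [
        text_prep.prepare_for_ngram_analysis(
            r["text"], tagger, doc_id=r["doc_id"], period=r["period"]
        )
        for r in corpus.documents.to_dict("records")
    ]

    # --- word discrimination --------------------------------------------
    stats = word_discrimination.compute_word_stats(
        word_streams, method=config.test_method
    )
    word_discrimination.retain_words(
        stats, p_max=config.p_max, or_low=config.or_low, or_high=config.or_high
    )
    word_stats = word_discrimination.word_stats_frame(stats)
    word_stats.to_csv(os.path.join(out, "word_stats.csv"), index=False)
    manifest["counts"]["words_tested"] = len(word_stats)
    manifest["counts"]["words_retained"] = int(word_stats["retained"].sum())

    # --- category analysis (planted categories when simulating) ----------
    category_stats = None
    if config.simulate:
        cats = [
            category_analysis.WordCategory(cid, cid, frozenset(words))
            for cid, words in synthetic_ehr.PLANTED_CATEGORIES.items()
        ]
        cat_rows = [
            {
                "category": s.category_id,
                "odds_ratio": s.odds_ratio,
                "a": s.table.a,
                "c": s.table.c,
            }
            for s in category_analysis.category_exposure(word_streams, cats)
        ]
        category_stats = pd.DataFrame(cat_rows)
        category_stats.to_csv(os.path.join(out, "category_stats.csv"), index=False)

    # --- n-gram Naive Bayes ----------------------------------------------
    feature_reports: dict[int, pd.DataFrame] = {}
    for n in config.ngram_orders:
        model = ngram_nb.fit_nb(ngram_streams, n=n, alpha=config.alpha)
        reports = ngram_nb.top_informative(model, ngram_streams, k=config.top_k)
        frame = ngram_nb.feature_report_frame(reports)
        frame.to_csv(os.path.join(out, f"features_{n}gram.csv"), index=False)
        feature_reports[n] = frame

    manifest["status"] = "complete"
    _write_manifest(out, manifest)
    return ReportBundle(
        out_dir=out,
        admissions=admissions,
        trajectory=trajectory,
        corpus_summary=summary,
        word_stats=word_stats,
        category_stats=category_stats,
        feature_reports=feature_reports,
        manifest=manifest,
    )


def _write_manifest(out: str, manifest: dict) -> None:
    with open(os.path.join(out, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
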