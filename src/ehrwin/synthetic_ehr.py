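"""Synthetic EHR cohort generator with known ground truth.

The real data this pipeline targets (mental-health trust free text linked to
national hospital-episode records) is access-restricted, so every downstream
stage is exercised against a generator whose parameters are the ground truth:

* **document arrival** — per patient, an inhomogeneous day-resolution Poisson
  process: baseline rate ``lambda0`` documents/day, rising linearly over the
  final ``ramp_length_days`` before a planted attempt date to
  ``lambda0 * ramp_multiplier`` (the observed phenomenon is a monotone rise in
  documentation starting ~60 days before an attempt; a linear ramp is the
  simplest mechanism reproducing it and is declared here, not estimated);
* **admissions** — each planted attempt becomes a hospital admission emitted
  as 1-3 contiguous consultant episodes (episode k ends the day episode k+1
  starts) carrying suicide-related ICD-10 codes, which exercises spell
  consolidation; distractor admissions carry non-suicide codes;
* **text** — tokens drawn from a small vocabulary; proximal documents (dated
  within 31 days before the attempt) use probabilities ``base * rho_w``
  renormalised, so each word's enrichment ratio rho_w is planted; multi-word
  vocabulary entries ("says that", "self-harm") plant enriched bigrams;
  document length is lognormal in token count, straddling the downstream
  100-character filter.

Determinism: one global seed; each patient gets an independent substream
derived by stable (SHA-256) hashing of the patient id, so generating more
patients never perturbs existing ones, and identical seed + config gives
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "VocabularyEntry",
    "DocLengthDistribution",
    "SimulationConfig",
    "GroundTruthManifest",
    "generate_cohort",
    "generate_document_text",
    "generate_period_corpus",
    "default_vocabulary",
    "write_outputs",
]

#: suicide-related codes planted on attempt admissions (within X60-X84,
#: Y10-Y34, Y87.0/Y87.2)
SUICIDE_CODES = (
    "X60", "X61", "X62.0", "X64", "X70", "X78", "X84",
    "Y10", "Y14.1", "Y20", "Y33", "Y34", "Y87.0", "Y87.2",
)
#: distractor codes, all outside the suicide-related ranges
NON_SUICIDE_CODES = ("F20.0", "F32.1", "J45", "I10", "S72.0", "Z50.1", "Y35", "X85")


@dataclass(frozen=True)
class VocabularyEntry:
    """One sampling unit: a word or a fixed multi-word phrase.

    ``base_prob`` is the distal-period probability (normalised over the
    vocabulary at config construction); the part-of-speech tag is generator
    metadata only — the analysis pipeline re-tags text with its own tagger.
    """

    word: str
    pos: str
    base_prob: float


@dataclass(frozen=True)
class DocLengthDistribution:
    """Lognormal distribution of document length in sampled tokens.

    Defaults give a median of ~22 tokens (~110 characters with the default
    vocabulary), so a substantial minority of documents fall at or under the
    100-character retention filter — as in real clinical corpora, where short
    administrative stubs are common.
    """

    mean_log: float = 3.1
    sigma_log: float = 0.6
    min_tokens: int = 1

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        draws = rng.lognormal(self.mean_log, self.sigma_log, size=size)
        return np.maximum(self.min_tokens, np.round(draws).astype(np.int64))


def default_vocabulary() -> tuple[list[VocabularyEntry], dict[str, float]]:
    """The default vocabulary and planted enrichment map.

    Enrichment ratios rho = proximal/distal probability ratio: overdose- and
    risk-related nouns and the five planted phrases are proximally enriched;
    care-plan/activity words and male pronouns are depleted (female pronouns
    mildly enriched), giving the pronoun-frequency shift.  The up- and
    down-enriched masses roughly balance so the proximal renormalising
    constant stays near 1 and rho = 1 words stay (near-)null.
    """
    entries = [
        # word, pos, base_prob, rho
        ("the", "DET", 0.060, 1.0),
        ("a", "DET", 0.027, 1.0),
        ("and", "CCONJ", 0.027, 1.0),
        ("to", "PART", 0.040, 1.0),
        ("of", "ADP", 0.030, 1.0),
        ("in", "ADP", 0.020, 1.0),
        ("on", "ADP", 0.018, 1.0),
        ("with", "ADP", 0.015, 1.0),
        ("at", "ADP", 0.010, 1.0),
        ("that", "SCONJ", 0.020, 1.0),
        ("not", "PART", 0.020, 1.5),
        ("no", "DET", 0.012, 1.5),
        ("there", "PRON", 0.010, 1.0),
        (".", "PUNCT", 0.050, 1.0),
        ("she", "PRON", 0.035, 1.5),
        ("he", "PRON", 0.035, 0.5),
        ("her", "PRON", 0.018, 1.5),
        ("his", "PRON", 0.018, 0.5),
        ("it", "PRON", 0.012, 1.0),
        ("be", "VERB", 0.040, 1.0),
        ("have", "VERB", 0.022, 1.0),
        ("do", "VERB", 0.015, 1.0),
        ("say", "VERB", 0.025, 1.2),
        ("report", "VERB", 0.018, 1.2),
        ("feel", "VERB", 0.018, 1.0),
        ("want", "VERB", 0.015, 1.0),
        ("attend", "VERB", 0.012, 0.3),
        ("improve", "VERB", 0.012, 0.3),
        ("sleep", "VERB", 0.012, 0.5),
        ("take", "VERB", 0.012, 1.0),
        ("patient", "NOUN", 0.040, 1.0),
        ("ward", "NOUN", 0.018, 0.5),
        ("overdose", "NOUN", 0.020, 4.0),
        ("medication", "NOUN", 0.022, 1.5),
        ("plan", "NOUN", 0.020, 0.3),
        ("care", "NOUN", 0.020, 0.3),
        ("family", "NOUN", 0.015, 0.5),
        ("mood", "NOUN", 0.018, 1.0),
        ("risk", "NOUN", 0.020, 3.0),
        ("staff", "NOUN", 0.012, 0.5),
        ("home", "NOUN", 0.012, 0.5),
        ("team", "NOUN", 0.012, 0.5),
        ("appointment", "NOUN", 0.014, 0.3),
        ("review", "NOUN", 0.014, 0.3),
        ("meal", "NOUN", 0.012, 0.3),
        ("activity", "NOUN", 0.012, 0.3),
        ("thought", "NOUN", 0.015, 1.0),
        # planted phrases: enriched bigrams after lemmatisation
        ("self-harm", "X", 0.006, 6.0),
        ("says that", "X", 0.005, 6.0),
        ("wants to", "X", 0.005, 6.0),
        ("reported that", "X", 0.005, 6.0),
        ("not want", "X", 0.005, 6.0),
    ]
    vocab = [VocabularyEntry(w, p, b) for w, p, b, _ in entries]
    enrichment = {w: r for w, p, b, r in entries}
    return vocab, enrichment


#: lemmatised bigrams planted via the phrase entries above
PLANTED_BIGRAMS = ("self harm", "say that", "want to", "report that", "not want")


def ngram_recovery_vocabulary() -> tuple[list[VocabularyEntry], dict[str, float]]:
    """A compact vocabulary for n-gram feature-recovery experiments.

    Only the five phrases are enriched (rho = 4); every standalone word —
    including each phrase's constituent tokens — has rho = 1 and a base
    probability of at least 0.03, for two reasons: common standalone
    constituents dilute the enrichment that "leaks" from a phrase onto its
    tokens (so context bigrams like "the self" stay well below the planted
    bigrams in class log-likelihood contrast), and the absence of rare words
    removes the low-count bigram tail whose smoothed contrasts are pure
    sampling noise.  With this design the planted bigrams are the only
    features whose contrast stands clear of everything else.
    """
    entries = [
        ("the", "DET", 0.085, 1.0),
        ("patient", "NOUN", 0.060, 1.0),
        ("be", "VERB", 0.065, 1.0),
        ("to", "PART", 0.050, 1.0),
        ("of", "ADP", 0.040, 1.0),
        ("and", "CCONJ", 0.040, 1.0),
        ("she", "PRON", 0.040, 1.0),
        ("he", "PRON", 0.040, 1.0),
        ("a", "DET", 0.030, 1.0),
        ("have", "VERB", 0.030, 1.0),
        ("feel", "VERB", 0.030, 1.0),
        ("mood", "NOUN", 0.030, 1.0),
        ("ward", "NOUN", 0.030, 1.0),
        (".", "PUNCT", 0.070, 1.0),
        ("that", "SCONJ", 0.060, 1.0),
        ("say", "VERB", 0.040, 1.0),
        ("report", "VERB", 0.040, 1.0),
        ("want", "VERB", 0.050, 1.0),
        ("not", "PART", 0.040, 1.0),
        ("self", "NOUN", 0.040, 1.0),
        ("harm", "NOUN", 0.050, 1.0),
        ("self-harm", "X", 0.008, 4.0),
        ("says that", "X", 0.008, 4.0),
        ("wants to", "X", 0.008, 4.0),
        ("reported that", "X", 0.008, 4.0),
        ("not want", "X", 0.008, 4.0),
    ]
    vocab = [VocabularyEntry(w, p, b) for w, p, b, _ in entries]
    enrichment = {w: r for w, p, b, r in entries}
    return vocab, enrichment


def null_words(config: "SimulationConfig") -> set[str]:
    """Single-token vocabulary words whose planted enrichment is truly null.

    Excludes constituents of enriched multi-token phrases: a word like
    "want" with rho = 1 still gains proximal mass through an enriched
    "wants to" phrase, so it is not a null word for recovery purposes.
    """
    from .text_prep import FallbackTagger

    lemma = FallbackTagger()
    phrase_lemmas: set[str] = set()
    for e in config.vocabulary:
        if " " in e.word or "-" in e.word:
            if config.enrichment.get(e.word, 1.0) != 1.0:
                for part in e.word.replace("-", " ").split():
                    phrase_lemmas.add(lemma(part)[1])
    out = set()
    for e in config.vocabulary:
        if " " in e.word or "-" in e.word or e.pos == "PUNCT":
            continue
        if config.enrichment.get(e.word, 1.0) != 1.0:
            continue
        if lemma(e.word)[1] in phrase_lemmas:
            continue
        out.add(e.word)
    return out

#: planted category structure over the word-analysis lemmas
PLANTED_CATEGORIES = {
    "RISK-DRUG": ("overdose", "medication"),
    "RISK-SH": ("self-harm", "risk"),
    "PROT-PLAN": ("plan", "care", "appointment", "review"),
    "PROT-ACT": ("meal", "activity", "ward", "home"),
}


@dataclass
class SimulationConfig:
    """Full specification of one synthetic cohort.

    Rates are per day; the attempt-rate ramp rises linearly from
    ``baseline_doc_rate`` at ``ramp_length_days`` before the attempt to
    ``baseline_doc_rate * ramp_multiplier`` at the attempt date.
    """

    n_patients: int = 500
    study_start: date = date(2010, 1, 1)
    study_end: date = date(2011, 12, 31)
    baseline_doc_rate: float = 0.2
    #: sd of the per-patient lognormal rate multiplier (mean 1).  Real
    #: cohorts have heavy-tailed contact rates — most patients are seen
    #: rarely, a few very often — which is what keeps the fraction monitored
    #: in a 30-day window well below 1; 0 gives a homogeneous cohort.
    rate_heterogeneity_sigma: float = 2.0
    ramp_multiplier: float = 3.0
    ramp_length_days: int = 60
    attempt_probability: float = 0.5
    distractor_admission_rate: float = 0.7  # mean distractor admissions/patient
    vocabulary: list[VocabularyEntry] = field(default_factory=list)
    enrichment: dict[str, float] = field(default_factory=dict)
    doc_length: DocLengthDistribution = field(default_factory=DocLengthDistribution)
    generate_text: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        if self.baseline_doc_rate < 0 or self.ramp_multiplier < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.attempt_probability <= 1.0:
            raise ValueError("attempt_probability must be in [0, 1]")
        if not self.vocabulary:
            self.vocabulary, default_rho = default_vocabulary()
            if not self.enrichment:
                self.enrichment = default_rho
        for w, r in self.enrichment.items():
            if r < 0:
                raise ValueError(f"negative enrichment for {w!r}")
        total = sum(e.base_prob for e in self.vocabulary)
        if total <= 0:
            raise ValueError("vocabulary base probabilities sum to zero")
        # normalise the base (distal) distribution once, at construction
        self.vocabulary = [
            VocabularyEntry(e.word, e.pos, e.base_prob / total)
            for e in self.vocabulary
        ]

    def period_probabilities(self) -> dict[str, np.ndarray]:
        """Distal = normalised base; proximal = base * rho, renormalised."""
        base = np.array([e.base_prob for e in self.vocabulary])
        rho = np.array([self.enrichment.get(e.word, 1.0) for e in self.vocabulary])
        prox = base * rho
        return {"distal": base, "proximal": prox / prox.sum()}


@dataclass
class GroundTruthManifest:
    """Everything the generator planted, for parameter-recovery tests."""

    seed: int
    attempt_dates: dict[str, str]  # patient_id -> ISO attempt (admit) date
    enrichment: dict[str, float]  # word -> planted rho
    doc_periods: dict[str, str]  # doc_id -> true period of its text model
    planted_categories: dict[str, tuple]
    planted_bigrams: tuple
    params: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    digest = hashlib.sha256(patient_id.encode()).digest()
    h = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31), h]))


def generate_document_text(
    period: str, config: SimulationConfig, rng: np.random.Generator
) -> str:
    """Sample one document's text from the period-specific multinomial."""
    if not config.vocabulary:
        raise ValueError("empty vocabulary")
    if period not in ("proximal", "distal"):
        raise ValueError(f"unknown period {period!r}")
    probs = config.period_probabilities()[period]
    n = int(config.doc_length.sample(rng, 1)[0])
    idx = rng.choice(len(config.vocabulary), size=n, p=probs)
    return " ".join(config.vocabulary[i].word for i in idx)


def _sample_texts(
    periods: list[str], config: SimulationConfig, rng: np.random.Generator
) -> list[str]:
    """Batch text sampling (one vocabulary draw per document batch)."""
    probs = config.period_probabilities()
    words = [e.word for e in config.vocabulary]
    lengths = config.doc_length.sample(rng, len(periods))
    texts = []
    for period, n in zip(periods, lengths):
        idx = rng.choice(len(words), size=int(n), p=probs[period])
        texts.append(" ".join(words[i] for i in idx))
    return texts


def _daily_rates(
    n_days: int,
    attempt_day: Optional[int],
    config: SimulationConfig,
    patient_rate: float,
) -> np.ndarray:
    lam = np.full(n_days, patient_rate)
    if attempt_day is None or config.ramp_length_days <= 0:
        return lam
    ramp = config.ramp_length_days
    for day in range(max(0, attempt_day - ramp), min(attempt_day, n_days)):
        frac = 1.0 - (attempt_day - day) / ramp  # 0 at ramp start, ->1 at attempt
        lam[day] = patient_rate * (1.0 + (config.ramp_multiplier - 1.0) * frac)
    return lam


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthManifest]:
    """Generate episode and document tables plus the ground-truth manifest.

    Returns
    -------
    episodes : DataFrame(patient_id, epi_start, epi_end, icd10_code)
    documents : DataFrame(doc_id, patient_id, date, text)
    manifest : GroundTruthManifest
    """
    n_days = (config.study_end - config.study_start).days + 1
    episode_rows: list[dict] = []
    doc_rows: list[dict] = []
    attempt_dates: dict[str, str] = {}
    doc_periods: dict[str, str] = {}

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        rng = _patient_rng(config.seed, pid)

        # heavy-tailed per-patient baseline rate, mean baseline_doc_rate
        sigma = config.rate_heterogeneity_sigma
        multiplier = rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
        patient_rate = config.baseline_doc_rate * multiplier

        attempt_day: Optional[int] = None
        if rng.random() < config.attempt_probability:
            # leave a full year + proximal window of history where possible
            lo = min(365 + 31, n_days - 1)
            attempt_day = int(rng.integers(lo, n_days))
            attempt_date = config.study_start + timedelta(days=attempt_day)
            attempt_dates[pid] = attempt_date.isoformat()
            episode_rows.extend(_attempt_episodes(pid, attempt_date, config, rng))

        # distractor admissions with non-suicide codes
        for _ in range(rng.poisson(config.distractor_admission_rate)):
            admit_day = int(rng.integers(0, n_days))
            duration = int(rng.integers(1, 8))
            start = config.study_start + timedelta(days=admit_day)
            end = min(start + timedelta(days=duration), config.study_end)
            episode_rows.append(
                {
                    "patient_id": pid,
                    "epi_start": start,
                    "epi_end": end,
                    "icd10_code": str(rng.choice(NON_SUICIDE_CODES)),
                }
            )

        # document arrival: day-resolution inhomogeneous Poisson
        counts = rng.poisson(_daily_rates(n_days, attempt_day, config, patient_rate))
        periods: list[str] = []
        dates: list[date] = []
        for day in np.flatnonzero(counts):
            d = config.study_start + timedelta(days=int(day))
            if attempt_day is not None and attempt_day - 31 <= day <= attempt_day - 1:
                period = "proximal"
            else:
                period = "distal"
            for _ in range(int(counts[day])):
                dates.append(d)
                periods.append(period)
        texts = (
            _sample_texts(periods, config, rng)
            if config.generate_text
            else [""] * len(periods)
        )
        for j, (d, period, text) in enumerate(zip(dates, periods, texts)):
            doc_id = f"{pid}-D{j:05d}"
            doc_rows.append(
                {"doc_id": doc_id, "patient_id": pid, "date": d, "text": text}
            )
            doc_periods[doc_id] = period

    episodes = pd.DataFrame(
        episode_rows, columns=["patient_id", "epi_start", "epi_end", "icd10_code"]
    )
    documents = pd.DataFrame(
        doc_rows, columns=["doc_id", "patient_id", "date", "text"]
    )
    manifest = GroundTruthManifest(
        seed=config.seed,
        attempt_dates=attempt_dates,
        enrichment=dict(config.enrichment),
        doc_periods=doc_periods,
        planted_categories={k: tuple(v) for k, v in PLANTED_CATEGORIES.items()},
        planted_bigrams=PLANTED_BIGRAMS,
        params={
            "n_patients": config.n_patients,
            "study_start": config.study_start.isoformat(),
            "study_end": config.study_end.isoformat(),
            "baseline_doc_rate": config.baseline_doc_rate,
            "ramp_multiplier": config.ramp_multiplier,
            "ramp_length_days": config.ramp_length_days,
            "attempt_probability": config.attempt_probability,
            "point_process": "piecewise-constant Poisson, linear rate ramp",
        },
    )
    return episodes, documents, manifest


def _attempt_episodes(
    pid: str, attempt_date: date, config: SimulationConfig, rng: np.random.Generator
) -> list[dict]:
    """One suicide admission split into 1-3 contiguous episodes."""
    duration = int(rng.integers(1, 11))
    discharge = attempt_date + timedelta(days=duration)
    n_epi = int(rng.integers(1, 4))
    if n_epi > 1 and duration >= n_epi:
        interior = sorted(
            int(x) for x in rng.choice(range(1, duration), size=n_epi - 1, replace=False)
        )
        bounds = [0, *interior, duration]
    else:
        bounds = [0, duration]
    rows = []
    for k in range(len(bounds) - 1):
        rows.append(
            {
                "patient_id": pid,
                "epi_start": attempt_date + timedelta(days=bounds[k]),
                "epi_end": attempt_date + timedelta(days=bounds[k + 1]),
                "icd10_code": str(rng.choice(SUICIDE_CODES)),
            }
        )
    return rows


def generate_period_corpus(
    config: SimulationConfig,
    n_proximal: int,
    n_distal: int,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Directly sample a labelled two-period corpus (no cohort machinery).

    Convenience for text-analysis recovery experiments where only the word
    distributions matter.  Returns DataFrame(doc_id, period, text).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    periods = ["proximal"] * n_proximal + ["distal"] * n_distal
    texts = _sample_texts(periods, config, rng)
    return pd.DataFrame(
        {
            "doc_id": [f"S{i:06d}" for i in range(len(periods))],
            "period": periods,
            "text": texts,
        }
    )


def write_outputs(
    outdir,
    episodes: pd.DataFrame,
    documents: pd.DataFrame,
    manifest: GroundTruthManifest,
) -> None:
    """Write episodes CSV, documents JSONL and manifest JSON to ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    episodes.to_csv(os.path.join(outdir, "episodes.csv"), index=False)
    with open(os.path.join(outdir, "documents.jsonl"), "w") as fh:
        for row in documents.to_dict("records"):
            row = dict(row)
            row["date"] = row["date"].isoformat()
            fh.write(json.dumps(row) + "\n")
    manifest.to_json(os.path.join(outdir, "manifest.json"))
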