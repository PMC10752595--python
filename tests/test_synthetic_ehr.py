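"""Ground-truth properties of the synthetic cohort generator."""

from collections import Counter
from datetime import date

import numpy as np
import pandas as pd
import pytest

from ehrwin.cohort import is_suicide_code
from ehrwin.synthetic_ehr import (
    DocLengthDistribution,
    SimulationConfig,
    VocabularyEntry,
    generate_cohort,
    generate_document_text,
    generate_period_corpus,
    null_words,
)

SMALL = dict(n_patients=30, study_start=date(2010, 1, 1), study_end=date(2011, 6, 30))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 0},
            {"study_start": date(2011, 1, 1), "study_end": date(2010, 1, 1)},
            {"baseline_doc_rate": -0.1},
            {"attempt_probability": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_period_probabilities_normalised(self):
        probs = SimulationConfig(**SMALL).period_probabilities()
        assert probs["distal"].sum() == pytest.approx(1.0)
        assert probs["proximal"].sum() == pytest.approx(1.0)


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        out1 = generate_cohort(SimulationConfig(seed=42, **SMALL))
        out2 = generate_cohort(SimulationConfig(seed=42, **SMALL))
        pd.testing.assert_frame_equal(out1[0], out2[0])
        pd.testing.assert_frame_equal(out1[1], out2[1])
        assert out1[2].attempt_dates == out2[2].attempt_dates

    def test_different_seeds_differ(self):
        docs1 = generate_cohort(SimulationConfig(seed=1, **SMALL))[1]
        docs2 = generate_cohort(SimulationConfig(seed=2, **SMALL))[1]
        assert not docs1.equals(docs2)

    def test_adding_patients_does_not_perturb_existing(self):
        small = generate_cohort(SimulationConfig(seed=9, **SMALL))[1]
        grown = generate_cohort(
            SimulationConfig(seed=9, **{**SMALL, "n_patients": 60})
        )[1]
        subset = grown[grown["patient_id"].isin(small["patient_id"].unique())]
        pd.testing.assert_frame_equal(
            small.reset_index(drop=True), subset.reset_index(drop=True)
        )


class TestCohortStructure:
    def test_no_attempts_no_suicide_codes(self):
        eps, _, man = generate_cohort(
            SimulationConfig(seed=5, attempt_probability=0.0, **SMALL)
        )
        assert man.attempt_dates == {}
        assert not any(is_suicide_code(c) for c in eps["icd10_code"])

    def test_every_attempt_has_matching_suicide_episode(self):
        eps, _, man = generate_cohort(SimulationConfig(seed=6, **SMALL))
        assert man.attempt_dates  # the fixture plants some attempts
        for pid, iso in man.attempt_dates.items():
            attempt = date.fromisoformat(iso)
            mine = eps[eps["patient_id"] == pid]
            starts = mine[mine["icd10_code"].map(is_suicide_code)]["epi_start"]
            assert attempt in set(starts)

    def test_documents_within_study_window(self):
        cfg = SimulationConfig(seed=7, **SMALL)
        _, docs, _ = generate_cohort(cfg)
        assert docs["date"].min() >= cfg.study_start
        assert docs["date"].max() <= cfg.study_end

    def test_flat_process_without_ramp(self):
        """ramp_multiplier = 1: document counts in the last 30 pre-attempt
        days match the 30 days before that (paired across patients)."""
        cfg = SimulationConfig(
            seed=8,
            n_patients=300,
            ramp_multiplier=1.0,
            rate_heterogeneity_sigma=0.0,
            generate_text=False,
        )
        _, docs, man = generate_cohort(cfg)
        last, prev = 0, 0
        for pid, iso in man.attempt_dates.items():
            attempt = pd.Timestamp(iso)
            offsets = (pd.to_datetime(docs[docs["patient_id"] == pid]["date"]) - attempt).dt.days
            last += ((offsets >= -30) & (offsets <= -1)).sum()
            prev += ((offsets >= -60) & (offsets <= -31)).sum()
        from scipy.stats import binomtest

        assert binomtest(last, last + prev, 0.5).pvalue > 0.001

    def test_ramp_raises_final_window_rate(self):
        """With the default x3 ramp over 60 days, mean documents in the final
        30 days clearly exceed a same-length window a year earlier."""
        cfg = SimulationConfig(seed=10, n_patients=300, generate_text=False)
        _, docs, man = generate_cohort(cfg)
        final, distal = 0, 0
        for pid, iso in man.attempt_dates.items():
            attempt = pd.Timestamp(iso)
            offsets = (pd.to_datetime(docs[docs["patient_id"] == pid]["date"]) - attempt).dt.days
            final += ((offsets >= -30) & (offsets <= -1)).sum()
            distal += ((offsets >= -365) & (offsets <= -336)).sum()
        assert final > 1.5 * distal


class TestDocumentText:
    def test_empty_vocabulary_rejected(self):
        cfg = SimulationConfig(**SMALL)
        object.__setattr__  # silence lint; config is mutable
        cfg.vocabulary = []
        with pytest.raises(ValueError):
            generate_document_text("proximal", cfg, np.random.default_rng(0))

    def test_uniform_enrichment_identical_distributions(self):
        cfg = SimulationConfig(**SMALL)
        cfg.enrichment = {}
        probs = cfg.period_probabilities()
        assert np.allclose(probs["proximal"], probs["distal"])

    def test_enrichment_renormalisation_closed_form(self):
        """A word with rho = 4 and base 0.05 in a tiny fixture vocabulary:
        its proximal share is 0.05 * 4 / (renormalising sum), with the sum
        computed by hand from the fixture."""
        vocab = [
            VocabularyEntry("overdose", "NOUN", 0.05),
            VocabularyEntry("patient", "NOUN", 0.60),
            VocabularyEntry("plan", "NOUN", 0.35),
        ]
        enrichment = {"overdose": 4.0, "patient": 1.0, "plan": 1.0}
        cfg = SimulationConfig(
            vocabulary=vocab, enrichment=enrichment, seed=3, **SMALL
        )
        expected_share = 0.05 * 4 / (0.05 * 4 + 0.60 + 0.35)
        idx = [e.word for e in cfg.vocabulary].index("overdose")
        assert cfg.period_probabilities()["proximal"][idx] == pytest.approx(
            expected_share
        )
        # and the empirical frequency agrees at 3 standard errors
        rng = np.random.default_rng(0)
        tokens = []
        for _ in range(400):
            tokens.extend(generate_document_text("proximal", cfg, rng).split())
        freq = Counter(tokens)["overdose"] / len(tokens)
        se = (expected_share * (1 - expected_share) / len(tokens)) ** 0.5
        assert abs(freq - expected_share) < 3 * se

    def test_degenerate_length_all_below_filter(self):
        """Three short tokens per document: every text is <= 100 characters,
        so the downstream length filter removes the whole corpus."""
        vocab = [VocabularyEntry(w, "NOUN", 1 / 3) for w in ("ab", "cde", "fg")]
        cfg = SimulationConfig(
            vocabulary=vocab,
            enrichment={},
            doc_length=DocLengthDistribution(np.log(3), 0.0, min_tokens=3),
            seed=4,
            **SMALL,
        )
        corpus = generate_period_corpus(cfg, 50, 50)
        assert (corpus["text"].str.len() <= 100).all()

    def test_unknown_period_rejected(self):
        cfg = SimulationConfig(**SMALL)
        with pytest.raises(ValueError):
            generate_document_text("middle", cfg, np.random.default_rng(0))


def test_null_words_exclude_phrase_constituents():
    cfg = SimulationConfig(**SMALL)
    nulls = null_words(cfg)
    assert "patient" in nulls and "mood" in nulls
    # enriched words and phrase constituents are not null
    for w in ("overdose", "risk", "she", "want", "say", "report"):
        assert w not in nulls
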