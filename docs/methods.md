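# Methods

`ehrwin` compares electronic-health-record (EHR) free-text documentation in
two risk periods around hospitalised suicide attempts: a **proximal** window
31–1 days before a suicide-related hospital admission and a **distal** window
365–300 days before one. The pipeline has three analytic arms — the
documentation *rate* (how often anything is written), document-level *word
use* (which words discriminate the periods), and *n-gram* context (which
word sequences a multinomial Naive Bayes classifier finds informative) —
plus a synthetic-EHR generator that stands in for the restricted clinical
data.

## Cohort definition

Hospital activity arrives as finished consultant episodes (patient id, start
and end date, ICD-10 code). Episodes whose day ranges overlap or abut (next
start ≤ current end) are merged into admissions ("spells"); a one-day gap
starts a new spell. The merge rule is our reading of "a continuous period of
episodes" at day resolution; the flag is an OR over member episodes. An
admission is suicide-related when any constituent code is in X60–X84
(intentional self-harm), Y10–Y34 (undetermined intent), or is exactly Y87.0
or Y87.2 (sequelae); the two intent groups are pooled throughout. Each
patient's *first attempt* is the admit date (not discharge) of the earliest
suicide-related admission inside the configurable study window — every
pre-attempt window counts backwards from hospital arrival.

## Monitoring level

`MonitoringLevel_W(t)` is the number of documents dated in the closed
interval `[t − W, t − 1]` divided by `W` (documents/day); the reference day
itself is excluded, and `W = 30` is the default. A patient is *under
monitoring* at `t` once at least one document exists strictly before `t`.
The attempt-aligned trajectory evaluates, for each day offset `d < 0`, the
fraction of under-monitoring patients with ≥ `min_docs` documents in the `W`
days before `attempt + d`. `min_docs` defaults to 1 ("at least one
document"); the stricter "more than one document" variant is exposed as
`min_docs = 2` because the source material is ambiguous between the two
readings — neither is presented as definitive.

## Corpus windows

A document is proximal if dated in `[admit − 31, admit − 1]` of *any*
suicide-related admission (anchoring to all admissions, not only the first,
is the default; a flag restricts to the first). It is distal if dated in
`[admit − 365, admit − 300]` of a suicide-related admission and — for
admissions after the patient's first — at least 300 days after the previous
suicide-related admission's *discharge* (the conservative endpoint choice;
the clearance rule's endpoint is not pinned down by its source). Documents
are deduplicated to the earliest qualifying admission, and only documents
with more than 100 raw characters (whitespace included) are retained.

A dual proximal/distal qualification would resolve to proximal (logged), but
under these exact rules it is provably unreachable: a distal document for a
non-first admission must be ≥ 300 days after the previous suicide discharge,
while a proximal document precedes some suicide admission by ≤ 31 days, and
a document before the patient's first admission cannot be proximal to any.
The precedence branch is therefore defensive only.

## Text preparation

Two token streams are derived from each document, both via a pluggable
per-token tagger mapping token → (Universal POS tag, lemma):

* **word mode** — nouns, pronouns and verbs keep their lemma; all other word
  classes are replaced by their POS label; punctuation dropped. Feeds the
  word and category analyses (placeholder labels are excluded from the word
  inventory).
* **n-gram mode** — every word is lemmatised, nothing is substituted, and
  punctuation is kept, so function words survive as features; hyphenated
  lemmas split ("self-harm" → "self harm"), making compounds visible as
  bigrams.

The bundled tagger is a closed lexicon (~200 entries covering the synthetic
vocabulary, English function words, and common verb inflections) with
light suffix stripping and a NOUN/identity fallback for unknown tokens. It
is deterministic and dependency-free, so the whole suite runs hermetically;
a statistical tagger can be plugged in for real clinical text but is never
required.

## Word discrimination

Each word gets a document-level presence/absence 2×2 table across the
periods. The odds ratio is the cross-product ratio with the
Haldane–Anscombe +0.5 correction on any zero cell; significance is the
two-sided Fisher exact test (exact at small counts — the source never names
its test, and a Yates-corrected chi-square is available for comparison;
reports name the test used). Words are retained when `p ≤ 0.05` (inclusive)
and OR strictly outside (0.66, 1.50). No multiple-testing correction is
applied by default, faithful to the raw-threshold filter being reproduced; a
Benjamini–Hochberg option exists. Manual curation (abbreviations, dates,
locations, ambiguous words) is supported as an exclusion list, not
replicated algorithmically.

## Categories and agreement

Clinician-defined word categories are plain-text word lists. A document is
*exposed* to a category if it contains ≥ 1 member lemma; category odds
ratios reuse the word machinery on the exposure table. When two annotators
assign the same words to the same category inventory, agreement is reported
as a confusion matrix, Cohen's kappa `(p_o − p_e)/(1 − p_e)`, and
per-category precision/recall/F1 with the category author as reference
(direction is a named parameter, since precision(A→B) = recall(B→A); the
degenerate single-category case defines kappa as 1 iff observed agreement is
1).

## N-gram Naive Bayes

Uni-, bi- and tri-gram representations are fitted *independently* as
two-class multinomial Naive Bayes models (class prior = document share;
feature likelihood with additive smoothing α = 1). Multinomial rather than
Bernoulli because per-document occurrence counts are an object of analysis.
The model is fitted on the full corpus — a descriptive feature-inspection
use, not a predictive claim. Informativeness of a feature is
`|log P(f | proximal) − log P(f | distal)|`; ties break by total frequency
then lexicographically; classification ties resolve to distal (the
reference class). The top-30 report adds each feature's document-presence
OR, mean occurrences per document over the whole corpus, and the
*distinctiveness threshold* t\*: the smallest per-document count at which
the indicator "count ≥ t" passes the word-retention gates — for very common
function words presence means nothing but high repetition can discriminate.
t\* depends on the corpus and on that specific criterion; it is one
defensible reading of "how often must a common word occur to be
distinctive", reported as such.

## Synthetic generator: what it emulates, and what a green test shows

The generator's world (all parameters are declared, none estimated):

* **Document arrival** — per-patient day-resolution Poisson process.
  Baseline rate λ0 = 0.2 documents/day rises *linearly* over the final 60
  days before a planted attempt to λ0 × 3 (the target phenomenon is a
  monotone "exponential-like" rise detectable from ~60 days out; a linear
  ramp is the simplest mechanism that reproduces it). Each patient's
  baseline is multiplied by a lognormal factor (mean 1, log-sd 2.0): real
  cohorts have heavy-tailed contact rates, and without heterogeneity every
  simulated patient would have ≥ 1 document in any 30-day window, which
  contradicts the observed ~35–45% monitored share the generator must
  emulate.
* **Admissions** — each attempt becomes an admission of 1–10 days emitted as
  1–3 contiguous episodes with suicide-range codes (exercising spell
  consolidation deterministically); distractor admissions (~Poisson(0.7) per
  patient) carry non-suicide codes. Half of patients receive an attempt,
  placed at least 396 days into the study so the distal window exists.
* **Text** — tokens drawn i.i.d. from a ~52-entry vocabulary; proximal
  documents use base × ρ_w probabilities, renormalised, so each word's
  enrichment ratio is planted (overdose/risk words up to ρ = 4, care-plan
  and activity words down to ρ = 0.3, a she/he pronoun shift at 1.5/0.5).
  Five multi-word entries plant enriched bigrams. The up- and down-enriched
  probability masses approximately balance so the renormalising constant
  stays near 1 and ρ = 1 words remain effectively null. Document length is
  lognormal in tokens (median ≈ 22, ≈ 110 characters), so a large minority
  of documents fall under the 100-character filter.
* **Determinism** — one seed; per-patient substreams derived by SHA-256
  hashing of the patient id, so enlarging the cohort never perturbs
  existing patients.

A separate compact vocabulary (`ngram_recovery_vocabulary`) backs the
bigram-recovery experiment: only the five phrases are enriched (ρ = 4), and
every phrase constituent also occurs standalone with probability ≥ 0.03.
The dilution matters: a phrase's enrichment "leaks" onto its constituent
tokens, and in the full vocabulary, products of leaked and unigram
enrichments (e.g. contexts of "overdose") legitimately rival the planted
bigrams' likelihood contrast. With diluted constituents and no rare words,
the planted bigrams' contrast stands clear of every context bigram and of
the low-count noise tail — so their recovery in the NB top-30 is a sharp
test of the featurisation + model + ranking chain, not of a lucky
vocabulary.

What the generator does **not** emulate: realistic clinical language (token
draws are i.i.d.; no syntax, negation or discourse), diagnosis-specific
risk, within-day timestamps, documentation gaps from service transfers, or
annotator behaviour. Green recovery tests therefore establish that the
pipeline recovers *planted* rate and enrichment structure at realistic
sample sizes — not that it would detect the (unknown) structure of real
records.

## Numerical choices

* Windows are closed day intervals; all boundary comparisons are tested
  explicitly (e.g. day −31 in, −32 out; reference day excluded).
* Threshold comparisons: `p ≤ 0.05` inclusive; OR bounds strict.
* Odds ratios use +0.5 on all four cells only when some cell is zero;
  p-values never use the correction (the exact test handles zeros).
* Fisher p-values come from scipy's log-space hypergeometric enumeration;
  tests verify exact agreement (< 1e-12) with an integer-arithmetic
  enumeration oracle over all tables with margins ≤ 20.
* The in-repo Naive Bayes is cross-checked against an exact-rational
  posterior enumeration and against scikit-learn's `MultinomialNB` (which
  is never used as the implementation).
* Degenerate cases: empty documents classify to the reference class;
  kappa with a single shared category is 1 iff agreement is perfect;
  categories with zero exposure are flagged, not dropped.

## Known limitations

* The bundled tagger is a closed lexicon: real clinical text would need the
  pluggable statistical tagger, whose lemmas may differ.
* The distinctiveness threshold t\* is criterion-relative; values from other
  corpora are not comparable.
* Aggregate results from the restricted source cohort (patient counts,
  specific word lists, category memberships) cannot be reproduced here;
  the category table arithmetic and worked examples are reproduced, and
  everything else is validated by construction on synthetic data.
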