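# asrt — automated story-recall scoring and validation

Story retelling is one of the most sensitive behavioral probes of episodic
memory in early Alzheimer disease and mild cognitive impairment (MCI).
Administering it remotely — a participant hears a short story on their
phone, retells it aloud, and the retelling is transcribed and scored
automatically — enables daily assessment with parallel stimuli, but it
requires a scoring pipeline whose every stage can be audited: transcript
normalization, an objective text-coverage score, transcription-quality
control, psychometric characterization, and longitudinal models of
performance and engagement.

`asrt` implements that stack for researchers in digital cognitive
assessment. Because no public story-recall corpus of this kind exists, the
package also ships a first-class synthetic study generator with known
ground truth, so every stage — from raw retelling text to mixed-model
effect estimates — is testable end to end.

## The score

A retelling is scored against its source story with **G-match**, a
proportional-recall index in [0, 1]. Both texts are normalized (lowercase,
punctuation stripped, filled pauses and partial words removed) and
segmented into sentence units. With source-unit embeddings $e_i$ (token
weights $w_i$) and retelling-unit embeddings $f_j$:

$$G = \frac{\sum_i w_i \,\max(0,\; s_i)}{\sum_i w_i},
\qquad s_i = \max_j \cos(e_i, f_j).$$

G-match is 1 for verbatim recall, 0 when no retelling unit resembles any
source unit, and in between equals the token-weighted fraction of source
content covered. Scoring is asymmetric: verbosity is not penalized. The
embedding backend is a pluggable contract; the default is an exact,
deterministic bag-of-words embedding (no model downloads), and any
sentence-embedding model can be wrapped behind the same interface.

Around the score:

- **`asrt.transcript_prep`** — normalization and word error rate
  (WER = (S+D+I)/reference length, minimum-edit-distance alignment)
  between manual and automatic transcripts, with per-participant and
  per-group QC summaries.
- **`asrt.psychometrics`** — pairwise-complete Spearman reliability
  matrices, convergent-validity correlations, Pearson chi-square for 2×2
  tables (no continuity correction), Welch t with Cohen d, and the
  multilevel conventions d = 2t/√df and AUC = Φ(d/√2).
- **`asrt.longitudinal`** — REML linear mixed models for performance
  (participant random intercept + day slope) over assessment days 2–7,
  and a random-intercept logistic adherence model over days 1–7 fitted by
  Gauss–Hermite marginal maximum likelihood.
- **`asrt.synthetic`** — the study generator: a bank of 18 short (~119
  words) and 18 long (~224 words) parallel stories, a two-group cohort
  with daily engagement, state self-reports, and retellings realized from
  a known latent recall proportion.
- **`asrt.pipeline` / `asrt` CLI** — end-to-end runs with hashed,
  reproducible output manifests.

## Worked example

```bash
python examples/score_retelling.py
```

```
G-match: 0.545
  source unit (weight  7 tokens): best similarity 0.882
  source unit (weight  9 tokens): best similarity 0.889
  source unit (weight 10 tokens): best similarity 0.000
```

The source has three sentences (7, 9 and 10 tokens). The retelling
paraphrases the first two (similarities 0.88–0.89) and omits the third
(0.0), so the score is the token-weighted mean
(7·0.882 + 9·0.889)/26 ≈ 0.545 — roughly "half the story came back."

`examples/simulate_and_score.py` runs the generator and scorer together
(50 participants): scored G-match correlates 0.96 with the intended recall
proportions, and group means separate by about the configured group
effect. `examples/longitudinal_models.py` fits the performance, adherence
and state models and prints effect tables next to the generating truths;
`examples/reliability_and_validity.py` and
`examples/wer_quality_control.py` cover the psychometrics and
transcription QC. Each script prints a short interpretation of its
numbers.

The same stages are available from the shell:

```bash
asrt simulate --out data/ --seed 17
asrt score --stories data/stories --manifest data/ --out scores.csv
asrt model --data data/ --scores scores.csv --model story --out fit.csv
```

## Documentation

`docs/methods.md` describes the scoring model and its assumptions, the
generator's calibration, numerical choices, and known limitations.
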