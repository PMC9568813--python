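# Methods

This note documents the models and procedures implemented in `asrt`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Scoring model

**Normalization.** All text comparison operates on normalized token
sequences: lowercased, punctuation stripped (any Unicode punctuation
category), filled pauses removed (default lexicon
um/uh/er/erm/eh/ah/mm/hmm/mhm, configurable), and partial words removed.
A partial word is a whitespace token ending in a trailing hyphen
(`"ca-"`), the common transcription convention for interrupted words; an
em dash is treated as clause punctuation attached to a complete word
(`"the—"` → `the`), not as a partial-word marker. Both the lexicon and the
marker set are parameters. Normalization is idempotent.

**Segmentation.** Texts are split into sentence units at `. ! ?`; each
unit is normalized, empty units are dropped, and unit weight is its token
count. Text containing no sentence delimiter at all (common in raw ASR
output) falls back to fixed windows of 15 tokens. A single punctuated
sentence is one unit — the window fallback applies only to unpunctuated
text, so a retelling consisting of one sentence is never artificially
split.

**G-match.** For source units with embeddings $e_i$ and weights $w_i$ and
retelling units $f_j$,

$$G = \sum_i w_i \max(0, \max_j \cos(e_i, f_j)) \Big/ \sum_i w_i.$$

Design choices, made where the score family is underdetermined:

- *Granularity* is the sentence; *weights* are source-unit token counts,
  so G reads as the token-weighted fraction of source content covered.
- *Aggregation* is best-match per source unit with negatives clamped to
  zero, which bounds G in [0, 1] with 1 attained exactly by verbatim
  recall.
- *Matching is non-exclusive*: one retelling sentence may serve several
  source sentences, because retellings routinely merge source material;
  an exclusivity constraint would add an assignment problem with no
  observable counterpart.
- *Scoring is asymmetric* (source→retelling coverage only). Intrusions
  and verbosity are not penalized; a score family penalizing them would
  need a principled trade-off parameter that nothing here identifies.

**Embedding backends.** The backend contract is: deterministic flag, a
name, and `embed(token_sequences) -> (n, dim)` L2-normalized rows. The
default `counts` backend embeds a unit as its exact bag-of-words count
vector over the vocabulary of the units passed in that call. Exactness is
the point: units sharing no token are exactly orthogonal, and a verbatim
unit achieves cosine exactly 1 (after an explicit 1e-12 snap against
normalization round-off). A fixed-dimension hashed variant would admit a
small collision probability that breaks these identities; since all units
of one comparison are embedded in a single call, per-call vocabulary
indexing loses nothing. A `trigram` backend (MD5-hashed character
3-grams, 4096 dims) is included as a deliberately different
representation for rank-stability checks; transformer sentence encoders
can be wrapped behind the same contract.

**Triplet means.** The mean of available story scores in a
(participant, day, recall-type) session. A session with no scored story is
missing, never 0: non-engagement and null recall are different outcomes,
and only an explicitly recorded empty retelling scores 0.

## Word error rate

WER = (substitutions + deletions + insertions) / reference length from a
unit-cost minimum-edit-distance alignment at the word level, computed
after normalization of both transcripts. Operation counts are read off one
optimal backtrace (ties broken substitution, then deletion, then
insertion); the total, and hence WER, is alignment-invariant. Group
contrasts aggregate per-recording WER → per-participant mean → Welch
two-sample t (Satterthwaite df) with Cohen d from the pooled SD.
Whether the original analyses averaged per recording or pooled token
counts per participant is not documented anywhere; per-participant
averaging was chosen because it makes the participant the unit of
analysis, consistent with a group test on ~150 participants yielding
~108 df.

## Psychometrics

- Spearman correlations throughout, average-rank ties, pairwise-complete
  deletion with a minimum of 3 complete pairs (engagement is optional, so
  each story pair is observed in a different participant subset).
  Constant columns yield a missing coefficient with a warning.
- Pearson chi-square on 2×2 tables without continuity correction,
  $X^2 = N(ad-bc)^2/((a{+}b)(c{+}d)(a{+}c)(b{+}d))$, 1 df. The
  uncorrected statistic is what the published group-composition tables
  reproduce; Yates-corrected values do not.
- Effect sizes: for mixed-model fixed effects, d = 2t/√(residual df),
  the multilevel-regression convention; residual df is taken as
  n_obs − n_fixed_effects (the fitted models do not expose a
  Satterthwaite df, and the convention is insensitive at these sizes).
  AUC equivalent: Φ(d/√2), the binormal equal-variance identity.
- No multiple-testing adjustment by default (raw coefficients are
  reported); Benjamini–Hochberg is available but off.
- Report percentages are rounded to 1 decimal place.

## Longitudinal models

**Performance.** G-match (per story, or per-session triplet mean) is
modeled with a linear mixed model restricted to assessment days 2–7 (the
days with novel stimuli common to both schedules): fixed effects of group
(reference CU), day (linear, uncentered), recall type (reference
immediate), story length (reference short), presentation order (1–3,
numeric; story-level model only), and sex/education/age; random
participant intercept and day slope with unstructured 2×2 covariance,
fitted by REML (statsmodels MixedLM, tolerance 1e-8, ≤200 iterations).
If the random-slope fit fails or lands on a singular covariance, the
model refits with a random intercept only and records the fallback in the
fit's warning list — never silently. Wald 95% intervals with t reference
(residual df as above).

**Adherence.** Daily engagement (≥1 retelling that day, days 1–7,
absent manifest rows = non-engagement) is a random-intercept logistic
model. statsmodels offers only Bayesian approximations for mixed GLMs,
and in pilot calibration their MAP estimates shrank a group log-odds of
−0.97 by ~17%, so the marginal maximum likelihood is implemented
directly: the random intercept is integrated by 31-node Gauss–Hermite
quadrature, the marginal likelihood maximized by BFGS (Nelder–Mead
polish), and standard errors taken from the numerical Hessian. On a
shared fixture the estimates, standard errors and random-intercept SD
match `lme4::glmer` (adaptive quadrature, nAGQ=25) to ~1e-3; that
cross-check is part of the test suite. Constant responses and runaway
log-odds (|β| > 15) raise a separation error rather than returning
estimates.

**State covariation.** The triplet model plus four daily self-report
covariates (mood, sleep, effort, mind-wandering; 7-point items entered as
given). Zero-variance state columns are dropped with a warning — constant
covariates are unidentifiable against the intercept — and an all-missing
column is an error.

## Synthetic study generator

The generator emulates the study design the analysis stack targets: a
78 + 73 cohort (CU vs MCI/mild AD), two administration schedules (7 or 8
remote days; day 1 repeats the three clinic stories, later days present
novel triplets alternating short/long by day), immediate and delayed
recall of each day's triplet, optional engagement, daily state
self-reports, and manual/automatic transcript pairs.

Latent recall acts on the proportion scale with an identity link,
mirroring the downstream linear model:

p = 0.57 − 0.11·group + 0.005·day − 0.02·delayed − 0.04·long
+ 0.02·order + 0.007·(mood−4) − 0.007·(mind-wandering−4)
+ u_i + s_i·day + δ_story + ε,  clamped to [0, 1],

with participant intercepts u_i ~ N(0, 0.10²), day slopes
s_i ~ N(0, 0.01²), residual ε ~ N(0, 0.08²), and per-story difficulty
δ ~ N(0, 0.01²). The fixed-effect values are the published longitudinal
estimates used as generating truths; the variance components are not
published anywhere and are generator choices, sized so that scores span
the unit interval without floor/ceiling effects and clamping stays rare
(the generator warns if more than 10% of cells clamp). Sleep and effort
are generated but carry no true effect — decoy covariates for the state
model. Story banks follow the published stimulus design: 18 short and 18
long stories with word counts ~ N(119, 4.83²) and N(224, 14.86²)
truncated positive.

Adherence is Bernoulli per participant-day-recall-type from a logistic
truth: intercept 1.24 (the logit of the published CU immediate-recall
adherence), group −0.97 (immediate) / −0.84 (delayed), day −0.04 and age
−0.07/yr (centered at 70) from the published estimates, −0.86 for
delayed recall under schedule 2, and a shared participant intercept
~ N(0, 1²). State items discretize a latent AR(1) (lag correlation 0.5)
to the 1–7 scale.

**Text realization.** A retelling keeps ⌈p·K⌉ of the story's K sentence
units (uniform without replacement, source order preserved), then applies
token dropout (3%), substitution (2%) and filler insertion (5%);
manual→automatic pairs are corrupted at total per-token rates 0.09 (CU)
and 0.13 (MCI/AD), split 60/25/15 across
substitutions/deletions/insertions — the published group WER levels as
generating truths. Each sentence unit draws from its own disjoint
vocabulary, so under the count backend a zero-noise retelling's G-match
equals its covered token-weight fraction *exactly*; the generator records
that fraction per retelling, pinning the full scoring chain to ground
truth.

**What the generator does not emulate.** Real English prose (token-pool
text suffices for the scoring contract, but no semantic paraphrase
exists, so transformer-backend behavior on paraphrase is not exercised);
distractor-task content between immediate and delayed recall (schedules
differ only in length, story mix and the delayed-adherence penalty); and
the unknown real spread of story difficulty. Passing the validation suite
therefore establishes the pipeline's internal correctness and the
estimators' calibration — not field performance on clinical speech.

## Validation design

Two different simulation designs are used deliberately:

- *Calibration* checks (CI coverage of the mixed-model estimators over
  replicated cohorts) simulate at the fitted model's own data-generating
  process — in particular with per-story difficulty off. A between-story
  cluster effect the model does not represent makes nominal coverage of
  the between-story length contrast unattainable for any estimator, which
  would test the model's robustness, not the estimator's correctness.
- *Robustness / chain* checks (end-to-end scoring, group-mean separation,
  WER recovery) use the full cohort defaults including story difficulty
  and text noise.

Sentence-count discretization (⌈p·K⌉) raises expected realized coverage
above p by roughly 1/(2K) — more for 7-unit short stories than 12-unit
long ones — so full-text simulations recover within-participant effects
(group, day, recall, order) cleanly while the length estimate absorbs a
small granularity offset. This is a property of realizing continuous
recall as whole sentences, not of the scorer; the recorded
coverage-fraction truth accounts for it exactly.

## Numerical choices

- Cosines within 1e-12 of 1 snap to 1, so verbatim recall scores exactly
  1.0; G is clipped to [0, 1] after weighting.
- The WER alignment uses int64 dynamic programming; ties in the
  backtrace prefer substitution, then deletion, then insertion.
- Chi-square margins of zero raise a degenerate-margin error rather than
  returning 0/0.
- Welch t with both groups at zero variance is an error unless the means
  are equal (then t = 0 by continuity).
- Mixed-model non-convergence is recorded on the fit and refuses effect
  tabulation; the random-slope→intercept fallback is logged.
- All generator randomness flows from one `numpy` Generator seeded by the
  caller; identical (config, seed) reproduces every file byte-for-byte.

## Known limitations

- The published headline clinical numbers (group d = 1.54, observed
  reliability means ρ ≈ 0.73, real WER group means) arise from
  unreleased participant data; here they serve as generating truths and
  conversion inputs, not as reproduction targets. Under the synthetic
  defaults the between-story reliability is ≈ 0.4–0.5, set by the chosen
  ability-variance ratio, lower than the published field values.
- d = 2t/√df depends on the residual-df convention; with
  df = n_obs − n_fixed the group |d| for a well-powered cohort exceeds
  the participant-level value a between-subject design would report.
  Treat per-effect d as comparable within this package, not across df
  conventions.
- The counts backend measures lexical overlap only; scoring paraphrase
  requires wrapping a semantic encoder behind the backend contract.
- Wald intervals throughout (profile likelihood is not implemented); at
  ~150 participants the difference is immaterial for the fixed effects.
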