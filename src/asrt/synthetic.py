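"""Synthetic study generator with known ground truth.

No public story-recall corpus accompanies this task family, so every
pipeline stage is exercised on a fully synthetic study: a story bank, a
two-group cohort (cognitively unimpaired vs MCI / mild AD), per-day
engagement, daily state self-reports, and retelling texts realized from a
known latent recall proportion. The generator's defaults are the study
conditions the validation targets: a 78 + 73 cohort, 18 short (~119-word)
and 18 long (~224-word) stories, daily triplets with immediate and delayed
recall over 7-8 remote days, and fixed-effect truths equal to the
reported longitudinal-model estimates.

Latent recall acts directly on the [0, 1] proportion scale (identity
link), mirroring the linear mixed model used downstream:

    p = b0 + b_group*g + b_day*day + b_recall*delayed + b_length*long
        + b_order*order + b_mood*(mood-4) + b_mw*(mw-4)
        + u_i + s_i*day + delta_story + eps,   clamped to [0, 1]

Retelling text is then the ceil(p*K) of the story's K sentence units
(sampled without replacement), token noise applied on top. Because each
sentence unit draws from its own disjoint vocabulary, a zero-noise
retelling's G-match under the count backend equals its covered
token-weight fraction exactly, which pins the whole scoring chain to the
generator's ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus_io import (
    Manifest,
    Participant,
    Story,
    StateReport,
    TranscriptRecord,
    write_manifest,
    write_story_bank,
)
from .gmatch import segment_units

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "generate_story_bank",
    "generate_cohort",
    "assign_latent_recall",
    "render_retellings",
    "render_asr_pair",
    "render_asr_pairs",
    "simulate_study",
    "write_study",
]

FILLERS = ("um", "uh", "er")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions; defaults are the validation-study targets."""

    # cohort
    n_cu: int = 78
    n_mci: int = 73
    # story bank: counts and token-count distributions per length class
    n_short: int = 18
    n_long: int = 18
    tokens_short: tuple[float, float] = (119.0, 4.83)
    tokens_long: tuple[float, float] = (224.0, 14.86)
    sentences_short: int = 7
    sentences_long: int = 12
    # fixed-effect truths on the recall-proportion scale
    intercept: float = 0.57
    effect_group: float = -0.11
    effect_day: float = 0.005
    effect_recall: float = -0.02     # delayed vs immediate
    effect_length: float = -0.04     # long vs short
    effect_order: float = 0.02       # per presentation position
    effect_mood: float = 0.007       # per point, centered at 4
    effect_mind_wandering: float = -0.007
    effect_sleep: float = 0.0        # decoys: reported, no true effect
    effect_effort: float = 0.0
    # variance components
    random_intercept_sd: float = 0.10
    random_slope_sd: float = 0.01
    residual_sd: float = 0.08
    story_difficulty_sd: float = 0.01
    # adherence truths (log-odds); age centered at 70 years
    adherence_intercept: float = 1.24
    adherence_group_immediate: float = -0.97
    adherence_group_delayed: float = -0.84
    adherence_day: float = -0.04
    adherence_age: float = -0.07
    adherence_schedule_delayed: float = -0.86
    adherence_random_sd: float = 1.0
    # retelling noise model
    token_dropout: float = 0.03
    token_substitution: float = 0.02
    filler_insertion: float = 0.05
    story_skip: float = 0.03
    # ASR corruption (total per-token error rate by group; sub/del/ins split)
    asr_rate_cu: float = 0.09
    asr_rate_mci: float = 0.13
    asr_split: tuple[float, float, float] = (0.60, 0.25, 0.15)
    # state-report AR(1)
    state_ar: float = 0.5

    def __post_init__(self):
        for name in ("token_dropout", "token_substitution", "filler_insertion",
                     "story_skip", "asr_rate_cu", "asr_rate_mci", "state_ar"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability")
        for name in ("n_cu", "n_mci", "n_short", "n_long",
                     "sentences_short", "sentences_long"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.asr_split) - 1.0) > 1e-9:
            raise ValueError("asr_split must sum to 1")


@dataclass
class SimulatedStudy:
    """A full synthetic study: inputs plus the truth that produced them."""

    config: SimulationConfig
    seed: int
    stories: dict[str, Story]
    manifest: Manifest
    adherence: pd.DataFrame       # participant_id, day, recall_type, adherent
    participant_truth: pd.DataFrame
    retelling_truth: pd.DataFrame
    clamp_fraction: float


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float, high: float = np.inf) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if low < v < high:
            return v
    raise RuntimeError("truncated normal rejection failed")  # pragma: no cover


def generate_story_bank(config: SimulationConfig,
                        seed: int | np.random.Generator) -> dict[str, Story]:
    """Generate the parallel story bank.

    Each story is a sequence of sentences over per-sentence disjoint token
    pools (tokens carry the story, sentence and position in their name, so
    no two sentences anywhere share a token). Word counts are drawn from
    truncated normal distributions per length class.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    bank: dict[str, Story] = {}
    plans = ([("s", i, config.tokens_short, config.sentences_short)
              for i in range(1, config.n_short + 1)]
             + [("l", i, config.tokens_long, config.sentences_long)
                for i in range(1, config.n_long + 1)])
    for prefix, idx, (mean, sd), n_sent in plans:
        sid = f"{prefix}{idx:02d}"
        n_tokens = int(round(_trunc_normal(rng, mean, sd, low=n_sent)))
        base, extra = divmod(n_tokens, n_sent)
        sentences = []
        for j in range(n_sent):
            length = base + (1 if j < extra else 0)
            toks = [f"{sid}u{j:02d}w{k:03d}" for k in range(length)]
            sentences.append(" ".join(toks).capitalize())
        text = ". ".join(sentences) + "."
        bank[sid] = Story(sid, "short" if prefix == "s" else "long",
                          text, n_tokens)
    return bank


def _sample_demographics(rng, pid: str, group: str) -> Participant:
    age = _trunc_normal(rng, 70.0, 5.8, 50.0, 85.0)
    sex = "female" if rng.random() < 0.58 else "male"
    education = float(np.clip(rng.normal(15.2, 3.1), 8, 22))
    country = "UK" if rng.random() < (0.85 if group == "CU" else 0.70) else "US"
    schedule = 1 if rng.random() < (0.51 if group == "CU" else 0.30) else 2
    amyloid = "positive" if rng.random() < (0.51 if group == "CU" else 0.44) \
        else "negative"
    if group == "CU":
        mmse = float(np.clip(round(rng.normal(28.9, 1.15)), 26, 30))
    else:
        mmse = float(np.clip(round(rng.normal(27.0, 2.07)), 23, 30))
    return Participant(pid, group, round(age, 1), sex, round(education, 1),
                       country, schedule, amyloid, mmse)


def _story_schedule(rng, config, participant: Participant,
                    stories: Mapping[str, Story]) -> dict[int, list[str]]:
    """Assign each remote day its triplet: novel stories, one length class
    per day, alternating classes from day 2 so both classes occur within
    every participant. Day 1 repeats the three clinic stories (long)."""
    short_ids = [s for s, st in stories.items() if st.length_class == "short"]
    long_ids = [s for s, st in stories.items() if st.length_class == "long"]
    clinic = long_ids[:3]
    short_pool = list(rng.permutation(short_ids))
    long_pool = list(rng.permutation([s for s in long_ids if s not in clinic]))
    n_days = 7 if participant.schedule == 1 else 8
    out = {1: list(clinic)}
    for day in range(2, n_days + 1):
        use_short = (day % 2 == 0)
        pool = short_pool if use_short else long_pool
        out[day] = [pool.pop() for _ in range(3)]
    return out


def generate_cohort(
    config: SimulationConfig, seed: int | np.random.Generator
) -> tuple[list[Participant], pd.DataFrame, list[StateReport], pd.DataFrame]:
    """Sample participants, daily adherence, and state reports.

    Adherence is Bernoulli from the configured logistic truth (shared
    participant random intercept across recall types; age centered at 70).
    State items discretize a latent AR(1) per participant and item. Returns
    (participants, adherence frame, state reports, participant truth).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    participants, truth_rows, adh_rows, state_reports = [], [], [], []
    groups = ["CU"] * config.n_cu + ["MCI_AD"] * config.n_mci
    for i, group in enumerate(groups):
        pid = f"p{i + 1:03d}"
        part = _sample_demographics(rng, pid, group)
        participants.append(part)
        u = rng.normal(0.0, config.random_intercept_sd)
        s = rng.normal(0.0, config.random_slope_sd)
        a = rng.normal(0.0, config.adherence_random_sd)
        truth_rows.append({"participant_id": pid, "group": group,
                           "latent_intercept": u, "latent_day_slope": s,
                           "adherence_intercept": a})
        g = 1.0 if group == "MCI_AD" else 0.0
        n_days = 7 if part.schedule == 1 else 8
        z = {item: rng.normal() for item in
             ("mood", "sleep", "mind_wandering", "effort")}
        for day in range(1, n_days + 1):
            state_vals = {}
            for item in z:
                z[item] = (config.state_ar * z[item]
                           + math.sqrt(1 - config.state_ar ** 2) * rng.normal())
                state_vals[item] = int(np.clip(round(4 + 1.5 * z[item]), 1, 7))
            engaged_any = False
            # one Bernoulli per recall type; the shared intercept a
            # correlates immediate and delayed engagement within a day
            for recall in ("immediate", "delayed"):
                eta = (config.adherence_intercept
                       + (config.adherence_group_immediate if recall == "immediate"
                          else config.adherence_group_delayed) * g
                       + config.adherence_day * day
                       + config.adherence_age * (part.age - 70.0)
                       + (config.adherence_schedule_delayed
                          if recall == "delayed" and part.schedule == 2 else 0.0)
                       + a)
                adherent = int(rng.random() < 1.0 / (1.0 + math.exp(-eta)))
                adh_rows.append({"participant_id": pid, "day": day,
                                 "recall_type": recall, "adherent": adherent,
                                 **state_vals})
                engaged_any = engaged_any or adherent
            if engaged_any:
                state_reports.append(StateReport(pid, day, state_vals["mood"],
                                                 state_vals["sleep"],
                                                 state_vals["mind_wandering"],
                                                 state_vals["effort"]))
    return (participants, pd.DataFrame(adh_rows), state_reports,
            pd.DataFrame(truth_rows))


def assign_latent_recall(
    participants: list[Participant],
    adherence: pd.DataFrame,
    stories: Mapping[str, Story],
    config: SimulationConfig,
    seed: int | np.random.Generator,
    participant_truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, float]:
    """Assign the intended recall proportion p to every adherent cell.

    Returns (truth frame, clamp fraction). A clamp fraction above 10%
    triggers a warning: the configured effects are pushing p outside
    [0, 1] too often for the identity-link model to stay faithful.
    """
    import warnings as _warnings

    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pmap = {p.participant_id: p for p in participants}
    if participant_truth is None:
        raise ValueError("participant_truth (latent effects) is required")
    tmap = participant_truth.set_index("participant_id")
    story_delta = {sid: rng.normal(0.0, config.story_difficulty_sd)
                   for sid in sorted(stories)}
    schedules = {p.participant_id:
                 _story_schedule(rng, config, p, stories) for p in participants}
    rows = []
    n_clamped = 0
    for rec in adherence.itertuples(index=False):
        if not rec.adherent:
            continue
        part = pmap[rec.participant_id]
        g = 1.0 if part.group == "MCI_AD" else 0.0
        u = tmap.loc[rec.participant_id, "latent_intercept"]
        s = tmap.loc[rec.participant_id, "latent_day_slope"]
        day_stories = schedules[rec.participant_id].get(rec.day, [])
        for order, sid in enumerate(day_stories, start=1):
            story = stories[sid]
            raw = (config.intercept
                   + config.effect_group * g
                   + config.effect_day * rec.day
                   + config.effect_recall * (rec.recall_type == "delayed")
                   + config.effect_length * (story.length_class == "long")
                   + config.effect_order * order
                   + config.effect_mood * (rec.mood - 4)
                   + config.effect_mind_wandering * (rec.mind_wandering - 4)
                   + config.effect_sleep * (rec.sleep - 4)
                   + config.effect_effort * (rec.effort - 4)
                   + u + s * rec.day + story_delta[sid]
                   + rng.normal(0.0, config.residual_sd))
            p = float(np.clip(raw, 0.0, 1.0))
            n_clamped += (p != raw)
            rows.append({"participant_id": rec.participant_id, "day": rec.day,
                         "story_id": sid, "recall_type": rec.recall_type,
                         "order": order, "p_intended": p, "p_raw": raw})
    truth = pd.DataFrame(rows)
    clamp_fraction = n_clamped / max(len(truth), 1)
    if clamp_fraction > 0.10:
        _warnings.warn(
            f"{100 * clamp_fraction:.1f}% of latent recall proportions were "
            "clamped to [0, 1]; the configured effects are likely "
            "inconsistent", stacklevel=2)
    return truth, clamp_fraction


def _corrupt_tokens(rng, tokens: list[str], dropout: float, substitution: float,
                    filler: float, tag: str) -> list[str]:
    out = []
    for tok in tokens:
        r = rng.random()
        if r < dropout:
            pass
        elif r < dropout + substitution:
            out.append(f"{tag}{rng.integers(0, 10 ** 6):06d}")
        else:
            out.append(tok)
        if filler and rng.random() < filler:
            out.append(FILLERS[int(rng.integers(0, len(FILLERS)))])
    return out


def render_retellings(
    truth: pd.DataFrame,
    stories: Mapping[str, Story],
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Realize retelling texts from intended recall proportions.

    A retelling keeps ceil(p*K) of the story's K sentence units (uniform
    sample without replacement, source order preserved), then applies
    token dropout/substitution and filler insertion. The returned truth
    frame adds ``coverage_fraction``, the covered token-weight share — the
    exact G-match a zero-noise retelling earns under the count backend.
    Stories are skipped (no row) at the configured rate, except that an
    engaged session always keeps at least its first story.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    unit_cache = {sid: segment_units(st.text) for sid, st in stories.items()}
    records: list[TranscriptRecord] = []
    truth = truth.copy().reset_index(drop=True)
    truth["coverage_fraction"] = np.nan
    truth["skipped"] = False
    session_last = truth.groupby(
        ["participant_id", "day", "recall_type"])["order"].transform("max")
    session_seen: dict[tuple, bool] = {}
    for i, row in enumerate(truth.itertuples(index=False)):
        key = (row.participant_id, row.day, row.recall_type)
        is_last = row.order == session_last.iloc[i]
        must_keep = is_last and not session_seen.get(key, False)
        if not must_keep and rng.random() < config.story_skip:
            truth.loc[i, "skipped"] = True
            continue
        session_seen[key] = True
        units = unit_cache[row.story_id]
        weights = np.array([u.weight for u in units], dtype=float)
        k_units = len(units)
        n_keep = min(math.ceil(row.p_intended * k_units), k_units)
        if n_keep == 0:
            truth.loc[i, "coverage_fraction"] = 0.0
            records.append(TranscriptRecord(row.participant_id, row.day,
                                            row.story_id, row.recall_type,
                                            row.order, "", "synthetic"))
            continue
        chosen = np.sort(rng.choice(k_units, size=n_keep, replace=False))
        truth.loc[i, "coverage_fraction"] = float(
            weights[chosen].sum() / weights.sum())
        sentences = []
        for j in chosen:
            toks = _corrupt_tokens(rng, list(units[j].tokens),
                                   config.token_dropout,
                                   config.token_substitution,
                                   config.filler_insertion, tag="xsub")
            if toks:
                sentences.append(" ".join(toks).capitalize())
        text = (". ".join(sentences) + ".") if sentences else ""
        records.append(TranscriptRecord(row.participant_id, row.day,
                                        row.story_id, row.recall_type,
                                        row.order, text, "synthetic"))
    return records, truth


def render_asr_pair(manual_text: str, total_rate: float,
                    split: tuple[float, float, float],
                    rng: np.random.Generator) -> str:
    """Corrupt a manual transcript into a synthetic ASR transcript."""
    p_sub, p_del, p_ins = (total_rate * f for f in split)
    tokens = manual_text.split()
    out = []
    for tok in tokens:
        r = rng.random()
        if r < p_del:
            continue
        if r < p_del + p_sub:
            out.append(f"asr{rng.integers(0, 10 ** 6):06d}")
        else:
            out.append(tok)
        if rng.random() < p_ins:
            out.append(f"asr{rng.integers(0, 10 ** 6):06d}")
    return " ".join(out)


def render_asr_pairs(
    transcripts: list[TranscriptRecord],
    participants: list[Participant],
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Manual/automatic transcript pairs at per-group corruption rates."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    group = {p.participant_id: p.group for p in participants}
    rows = []
    for rec in transcripts:
        if not rec.text:
            continue
        rate = (config.asr_rate_cu if group[rec.participant_id] == "CU"
                else config.asr_rate_mci)
        rows.append({"participant_id": rec.participant_id, "day": rec.day,
                     "story_id": rec.story_id, "recall_type": rec.recall_type,
                     "manual": rec.text,
                     "automatic": render_asr_pair(rec.text, rate,
                                                  config.asr_split, rng)})
    return pd.DataFrame(rows)


def simulate_study(config: SimulationConfig | None = None,
                   seed: int = 0) -> SimulatedStudy:
    """Generate a complete study from one seed (end-to-end deterministic)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    stories = generate_story_bank(config, rng)
    participants, adherence, state_reports, part_truth = \
        generate_cohort(config, rng)
    truth, clamp_fraction = assign_latent_recall(
        participants, adherence, stories, config, rng, part_truth)
    transcripts, truth = render_retellings(truth, stories, config, rng)
    manifest = Manifest(participants, transcripts, state_reports)
    return SimulatedStudy(config, seed, stories, manifest, adherence,
                          part_truth, truth, clamp_fraction)


def write_study(study: SimulatedStudy, directory: str | Path) -> None:
    """Write the file set the loaders consume, plus truth tables under truth/."""
    directory = Path(directory)
    write_story_bank(study.stories, directory / "stories")
    write_manifest(study.manifest, directory)
    truth_dir = directory / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    study.participant_truth.to_csv(truth_dir / "participants.csv", index=False)
    study.retelling_truth.to_csv(truth_dir / "retellings.csv", index=False)
    study.adherence.to_csv(truth_dir / "adherence.csv", index=False)
    pd.Series(asdict(study.config)).to_json(truth_dir / "config.json")
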