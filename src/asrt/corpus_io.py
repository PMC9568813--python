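"""Data model and CSV/text I/O for story banks, manifests and scores.

Everything on disk is plain text: a story bank is a directory of ``.txt``
files (or a single CSV), and the cohort is three CSV manifests —
``participants.csv``, ``transcripts.csv``, ``state.csv`` — plus
``scores.csv`` written by the scorer. Transcript text may be inline (a
``text`` column) or by relative file path (``text_path``); inline wins if
both are present. An empty text field is a recorded null response (the
participant engaged but produced nothing scoreable); an absent row means
non-engagement, which matters for adherence analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .transcript_prep import normalize_transcript

__all__ = [
    "Story",
    "Participant",
    "TranscriptRecord",
    "StateReport",
    "ScoreRecord",
    "Manifest",
    "load_story_bank",
    "write_story_bank",
    "load_manifest",
    "write_manifest",
    "load_scores",
    "write_scores",
    "write_model_report",
]

GROUPS = ("CU", "MCI_AD")
RECALL_TYPES = ("immediate", "delayed")
LENGTH_CLASSES = ("short", "long")
DAY_RANGE = (1, 8)


@dataclass(frozen=True)
class Story:
    """A source stimulus text."""

    story_id: str
    length_class: str
    text: str
    word_count: int

    def __post_init__(self):
        if not self.text.strip():
            raise ValueError(f"empty story text for {self.story_id!r}")
        if self.length_class not in LENGTH_CLASSES:
            raise ValueError(
                f"unknown length class {self.length_class!r} for {self.story_id!r}")


@dataclass(frozen=True)
class Participant:
    participant_id: str
    group: str
    age: float
    sex: str
    education: float
    country: str = "UK"
    schedule: int = 1
    amyloid: str = "unknown"
    mmse: float = float("nan")

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.schedule not in (1, 2):
            raise ValueError(f"schedule must be 1 or 2, got {self.schedule!r}")
        if not np.isnan(self.mmse) and not (0 <= self.mmse <= 30):
            raise ValueError(f"mmse out of range: {self.mmse}")


@dataclass(frozen=True)
class TranscriptRecord:
    """One retelling: participant x day x story x recall type x order."""

    participant_id: str
    day: int
    story_id: str
    recall_type: str
    order: int
    text: str = ""
    provenance: str = "automatic"

    def __post_init__(self):
        if not DAY_RANGE[0] <= self.day <= DAY_RANGE[1]:
            raise ValueError(
                f"day {self.day} outside remote range {DAY_RANGE} "
                f"({self.participant_id}/{self.story_id})")
        if self.recall_type not in RECALL_TYPES:
            raise ValueError(f"unknown recall type {self.recall_type!r}")
        if self.order not in (1, 2, 3):
            raise ValueError(f"order must be in 1..3, got {self.order!r}")
        if self.provenance not in ("manual", "automatic", "synthetic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.day, self.story_id, self.recall_type)


@dataclass(frozen=True)
class StateReport:
    """Daily 7-point self-report: mood, sleep, mind-wandering, effort."""

    participant_id: str
    day: int
    mood: int
    sleep: int
    mind_wandering: int
    effort: int

    def __post_init__(self):
        for name in ("mood", "sleep", "mind_wandering", "effort"):
            v = getattr(self, name)
            if not 1 <= v <= 7:
                raise ValueError(f"{name}={v} outside 1..7 "
                                 f"({self.participant_id} day {self.day})")


@dataclass(frozen=True)
class ScoreRecord:
    participant_id: str
    day: int
    story_id: str
    recall_type: str
    order: int
    gmatch: float
    triplet_mean: float = float("nan")

    def __post_init__(self):
        if not 0.0 <= self.gmatch <= 1.0:
            raise ValueError(f"gmatch {self.gmatch} outside [0, 1]")


@dataclass
class Manifest:
    """A validated cohort dataset."""

    participants: list[Participant]
    transcripts: list[TranscriptRecord]
    state_reports: list[StateReport]

    def participants_frame(self) -> pd.DataFrame:
        return _to_frame(self.participants, Participant)

    def transcripts_frame(self) -> pd.DataFrame:
        return _to_frame(self.transcripts, TranscriptRecord)

    def state_frame(self) -> pd.DataFrame:
        return _to_frame(self.state_reports, StateReport)


def _to_frame(records: Sequence, cls) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(cls)]
    return pd.DataFrame([dataclasses.astuple(r) for r in records], columns=cols)


# ---------------------------------------------------------------------------
# story banks


def _infer_length_class(story_id: str, word_count: int) -> str:
    if story_id[:1] == "s":
        return "short"
    if story_id[:1] == "l":
        return "long"
    return "short" if word_count <= 170 else "long"


def load_story_bank(path: str | Path) -> dict[str, Story]:
    """Load a story bank from a directory of .txt files or a single CSV.

    Directory: each ``<story_id>.txt`` holds one story; length class is
    inferred from the id prefix (``s``/``l``) or the word count. CSV:
    columns ``story_id``, ``text`` and optionally ``length_class``. Word
    counts are whitespace tokens after normalization.
    """
    path = Path(path)
    rows: list[tuple[str, str, str | None]] = []
    if path.is_dir():
        files = sorted(path.glob("*.txt"))
        if not files:
            raise ValueError(f"no .txt stories found in {path}")
        for f in files:
            rows.append((f.stem, f.read_text(encoding="utf-8"), None))
    else:
        df = pd.read_csv(path, dtype={"story_id": str})
        if "story_id" not in df or "text" not in df:
            raise ValueError("story CSV needs 'story_id' and 'text' columns")
        for rec in df.itertuples(index=False):
            lc = getattr(rec, "length_class", None)
            text = rec.text if isinstance(rec.text, str) else ""
            rows.append((rec.story_id, text, lc))
    bank: dict[str, Story] = {}
    for story_id, text, lc in rows:
        if story_id in bank:
            raise ValueError(f"duplicate story id {story_id!r}")
        if not isinstance(text, str) or not text.strip():
            raise ValueError(f"empty story text for {story_id!r}")
        wc = normalize_transcript(text).n
        bank[story_id] = Story(story_id, lc or _infer_length_class(story_id, wc),
                               text, wc)
    return bank


def write_story_bank(bank: Mapping[str, Story], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for story in bank.values():
        (directory / f"{story.story_id}.txt").write_text(story.text,
                                                         encoding="utf-8")


# ---------------------------------------------------------------------------
# manifests


def _read_text_field(row, base_dir: Path) -> str:
    text = getattr(row, "text", None)
    if isinstance(text, str) and text:
        return text
    text_path = getattr(row, "text_path", None)
    if isinstance(text_path, str) and text_path:
        return (base_dir / text_path).read_text(encoding="utf-8")
    return ""


def load_manifest(
    directory: str | Path,
    story_bank: Mapping[str, Story] | None = None,
) -> Manifest:
    """Load and validate participants/transcripts/state CSVs.

    ``directory`` must contain ``participants.csv`` and ``transcripts.csv``;
    ``state.csv`` is optional. When a story bank is given, transcript
    ``story_id`` values are checked against it. Duplicate
    (participant, day, story, recall type) rows are rejected.
    """
    directory = Path(directory)
    pdf = pd.read_csv(directory / "participants.csv",
                      dtype={"participant_id": str})
    participants = [
        Participant(
            participant_id=r.participant_id, group=r.group, age=float(r.age),
            sex=r.sex, education=float(r.education),
            country=getattr(r, "country", "UK"),
            schedule=int(getattr(r, "schedule", 1)),
            amyloid=getattr(r, "amyloid", "unknown"),
            mmse=float(getattr(r, "mmse", float("nan"))),
        )
        for r in pdf.itertuples(index=False)
    ]
    known_pids = {p.participant_id for p in participants}

    tdf = pd.read_csv(directory / "transcripts.csv",
                      dtype={"participant_id": str, "story_id": str},
                      keep_default_na=False, na_values=[])
    transcripts: list[TranscriptRecord] = []
    seen: set[tuple] = set()
    for r in tdf.itertuples(index=False):
        if story_bank is not None and r.story_id not in story_bank:
            raise ValueError(f"unknown story {r.story_id!r} in transcripts.csv")
        if r.participant_id not in known_pids:
            raise ValueError(f"unknown participant {r.participant_id!r} "
                             "in transcripts.csv")
        rec = TranscriptRecord(
            participant_id=r.participant_id, day=int(r.day), story_id=r.story_id,
            recall_type=r.recall_type, order=int(r.order),
            text=_read_text_field(r, directory),
            provenance=getattr(r, "provenance", "automatic") or "automatic",
        )
        if rec.key in seen:
            raise ValueError(f"duplicate transcript for {rec.key}")
        seen.add(rec.key)
        transcripts.append(rec)

    state: list[StateReport] = []
    state_path = directory / "state.csv"
    if state_path.exists():
        sdf = pd.read_csv(state_path, dtype={"participant_id": str})
        state = [
            StateReport(r.participant_id, int(r.day), int(r.mood), int(r.sleep),
                        int(r.mind_wandering), int(r.effort))
            for r in sdf.itertuples(index=False)
        ]
    return Manifest(participants, transcripts, state)


def write_manifest(manifest: Manifest, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest.participants_frame().to_csv(directory / "participants.csv",
                                         index=False)
    manifest.transcripts_frame().to_csv(directory / "transcripts.csv",
                                        index=False)
    if manifest.state_reports:
        manifest.state_frame().to_csv(directory / "state.csv", index=False)


# ---------------------------------------------------------------------------
# scores and model reports

SCORE_COLUMNS = ["participant_id", "day", "story_id", "recall_type", "order",
                 "gmatch", "triplet_mean"]


def write_scores(scores: pd.DataFrame | Iterable[ScoreRecord],
                 path: str | Path) -> None:
    """Write score records; round-trips losslessly through load_scores."""
    if not isinstance(scores, pd.DataFrame):
        scores = _to_frame(list(scores), ScoreRecord)
    scores.loc[:, SCORE_COLUMNS].to_csv(path, index=False)


def load_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "story_id": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scores file missing columns {sorted(missing)}")
    bad = df[(df["gmatch"] < 0) | (df["gmatch"] > 1)]
    if len(bad):
        raise ValueError("gmatch values outside [0, 1] in scores file")
    return df


def write_model_report(fit, path: str | Path) -> None:
    """Write a fitted model's coefficient table (one row per fixed effect)."""
    fit.coefficients.to_csv(path, index=False)
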