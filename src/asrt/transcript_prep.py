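"""Transcript normalization and word-error-rate QC.

Retellings arrive either as manual transcripts (verbatim, including
commentary, filled pauses and partial words) or as automatic (ASR)
transcripts. Before any text comparison both are normalized the same way:
punctuation removed, text lowercased, filled pauses and partial words
dropped. Word error rate between the two transcript sources is the number
of word-level edit operations per manual-transcript word.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FILLER_LEXICON",
    "DEFAULT_PARTIAL_MARKERS",
    "TokenSequence",
    "WerResult",
    "normalize_transcript",
    "word_error_rate",
    "cohort_wer",
]

#: Filled-pause tokens removed during normalization. The manual
#: transcription protocol transcribes filled pauses verbatim; these are the
#: common English forms.
DEFAULT_FILLER_LEXICON = frozenset(
    {"um", "uh", "er", "erm", "eh", "ah", "mm", "hmm", "mhm"}
)

#: A token ending in one of these marks an interrupted (partial) word in a
#: manual transcript, e.g. "ca-". The em dash is deliberately *not* a
#: default marker: transcribers use it as clause punctuation attached to a
#: complete word ("the—"), which must survive as "the".
DEFAULT_PARTIAL_MARKERS = ("-",)


@dataclass(frozen=True)
class TokenSequence:
    """An ordered, normalized word sequence."""

    tokens: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.tokens)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def text(self) -> str:
        return " ".join(self.tokens)


@dataclass(frozen=True)
class WerResult:
    """Word-level edit-distance summary for one manual/automatic pair."""

    substitutions: int
    deletions: int
    insertions: int
    ref_len: int

    @property
    def wer(self) -> float:
        return (self.substitutions + self.deletions + self.insertions) / self.ref_len


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


_WS = re.compile(r"\s+")


def normalize_transcript(
    text: str,
    filler_lexicon: Iterable[str] = DEFAULT_FILLER_LEXICON,
    partial_markers: Sequence[str] = DEFAULT_PARTIAL_MARKERS,
) -> TokenSequence:
    """Lowercase, strip punctuation, drop fillers and partial words.

    The operation is idempotent: applying it to its own output is a no-op.
    Empty or punctuation-only input yields an empty sequence.

    Parameters
    ----------
    text:
        Raw transcript text (any UTF-8 string).
    filler_lexicon:
        Lowercased filled-pause tokens to remove (compared after
        punctuation stripping).
    partial_markers:
        Suffixes marking an interrupted word; a whitespace token ending in
        one of these is removed entirely before punctuation stripping.
    """
    fillers = frozenset(f.lower() for f in filler_lexicon)
    out: list[str] = []
    for raw in _WS.split(text.lower().strip()):
        if not raw:
            continue
        if any(len(raw) > len(m) and raw.endswith(m) for m in partial_markers):
            continue
        word = "".join(ch for ch in raw if not _is_punct(ch))
        if not word or word in fillers:
            continue
        out.append(word)
    return TokenSequence(tuple(out))


def word_error_rate(
    reference: TokenSequence | Sequence[str],
    hypothesis: TokenSequence | Sequence[str],
) -> WerResult:
    """Word error rate via minimum-edit-distance alignment (unit costs).

    WER = (substitutions + deletions + insertions) / reference length. It
    can exceed 1 for very noisy hypotheses. Edit-operation counts are taken
    from one optimal alignment (ties broken substitution > deletion >
    insertion); the total count, hence the WER, is alignment-invariant.
    """
    ref = tuple(reference)
    hyp = tuple(hypothesis)
    if len(ref) == 0:
        raise ValueError("empty reference")
    nr, nh = len(ref), len(hyp)
    dist = np.zeros((nr + 1, nh + 1), dtype=np.int64)
    dist[:, 0] = np.arange(nr + 1)
    dist[0, :] = np.arange(nh + 1)
    for i in range(1, nr + 1):
        ri = ref[i - 1]
        row, prev = dist[i], dist[i - 1]
        for j in range(1, nh + 1):
            sub = prev[j - 1] + (ri != hyp[j - 1])
            row[j] = min(sub, prev[j] + 1, row[j - 1] + 1)
    s = d = ins = 0
    i, j = nr, nh
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dist[i, j] == dist[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]):
            s += ref[i - 1] != hyp[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and dist[i, j] == dist[i - 1, j] + 1:
            d += 1
            i -= 1
        else:
            ins += 1
            j -= 1
    return WerResult(int(s), int(d), int(ins), nr)


def cohort_wer(
    pairs: pd.DataFrame,
    participants: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("CU", "MCI_AD"),
    filler_lexicon: Iterable[str] = DEFAULT_FILLER_LEXICON,
) -> dict:
    """Per-recording WER, participant means and group contrast.

    ``pairs`` needs columns ``participant_id``, ``manual``, ``automatic``
    (raw texts; both are normalized here). Recording-level WERs are
    averaged per participant; the group contrast (Welch two-sample t with
    Satterthwaite df, Cohen d from the pooled SD) is computed on the
    participant-level means, so each participant contributes one unit.

    Returns a dict with ``recordings`` and ``participants`` DataFrames,
    ``group_means`` and the ``contrast`` (t, df, p, d).
    """
    from .psychometrics import welch_t  # local import: avoid cycle

    if len(pairs) == 0:
        raise ValueError("no manual/automatic transcript pairs available")
    rows = []
    for rec in pairs.itertuples(index=False):
        ref = normalize_transcript(rec.manual, filler_lexicon)
        hyp = normalize_transcript(rec.automatic, filler_lexicon)
        res = word_error_rate(ref, hyp)
        rows.append((rec.participant_id, res.substitutions, res.deletions,
                     res.insertions, res.ref_len, res.wer))
    recordings = pd.DataFrame(
        rows, columns=["participant_id", "substitutions", "deletions",
                       "insertions", "ref_len", "wer"])
    per_part = (recordings.groupby("participant_id", sort=True)["wer"]
                .mean().rename("mean_wer").reset_index())
    pmap = participants.set_index("participant_id")[group_col]
    per_part[group_col] = per_part["participant_id"].map(pmap)
    ga = per_part.loc[per_part[group_col] == groups[0], "mean_wer"].to_numpy()
    gb = per_part.loc[per_part[group_col] == groups[1], "mean_wer"].to_numpy()
    group_means = {groups[0]: float(np.mean(ga)) if len(ga) else np.nan,
                   groups[1]: float(np.mean(gb)) if len(gb) else np.nan}
    contrast = None
    if len(ga) >= 2 and len(gb) >= 2:
        contrast = welch_t(ga, gb)
    return {
        "recordings": recordings,
        "participants": per_part,
        "group_means": group_means,
        "overall_mean": float(per_part["mean_wer"].mean()),
        "contrast": contrast,
    }
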