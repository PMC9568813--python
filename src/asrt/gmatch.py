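"""G-match: embedding-based proportional-recall scoring.

A retelling is scored against its source story by (1) normalizing both
texts, (2) segmenting them into sentence units, (3) embedding every unit
with a deterministic text-embedding backend, and (4) taking, for each
source unit, the best cosine similarity over retelling units. G-match is
the token-count-weighted mean of those best similarities (negatives
clamped to zero), an index of the proportion of source content present in
the retelling:

    G = sum_i w_i * max(0, s_i) / sum_i w_i,   s_i = max_j cos(e_i, f_j)

where e_i are source-unit embeddings, f_j retelling-unit embeddings and
w_i source-unit token counts. G is 1 for a verbatim retelling and 0 when
no retelling unit resembles any source unit. Scoring is asymmetric:
coverage of the source is rewarded, extra material in the retelling is not
penalized.

The embedding backend is a pluggable contract; the default is an exact
bag-of-words count embedding (deterministic, dependency-free). Any object
with ``name``, ``deterministic`` and an ``embed(token_sequences) ->
(n, dim) L2-normalized array`` method conforms — e.g. a sentence
transformer wrapper.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .transcript_prep import (
    DEFAULT_FILLER_LEXICON,
    TokenSequence,
    normalize_transcript,
)

__all__ = [
    "TextUnit",
    "EmbeddingBackend",
    "CountsBackend",
    "TrigramBackend",
    "GmatchResult",
    "segment_units",
    "embed_units",
    "gmatch",
    "triplet_mean",
    "get_backend",
]

_SENTENCE_SPLIT = re.compile(r"[.!?]+")


@dataclass(frozen=True)
class TextUnit:
    """One scoring unit (a sentence, or a token window as fallback)."""

    unit_id: str
    tokens: tuple[str, ...]

    @property
    def weight(self) -> int:
        """Token count; used as the unit's weight in the G-match sum."""
        return len(self.tokens)


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract for text-embedding backends."""

    name: str
    deterministic: bool

    def embed(self, units: Sequence[Sequence[str]]) -> np.ndarray:
        """Return one L2-normalized row vector per token sequence."""
        ...


class CountsBackend:
    """Exact bag-of-words count embedding (the default backend).

    The vocabulary is built from the token sequences of each call, so
    vectors are exact: two units share a nonzero cosine iff they share a
    token, and disjoint-vocabulary units are exactly orthogonal. All units
    entering one G-match comparison are embedded in a single call, which is
    the only comparability the score requires.
    """

    name = "counts"
    deterministic = True

    def embed(self, units: Sequence[Sequence[str]]) -> np.ndarray:
        vocab: dict[str, int] = {}
        for unit in units:
            for tok in unit:
                vocab.setdefault(tok, len(vocab))
        mat = np.zeros((len(units), max(len(vocab), 1)), dtype=float)
        for i, unit in enumerate(units):
            for tok in unit:
                mat[i, vocab[tok]] += 1.0
        return _l2_normalize(mat)


class TrigramBackend:
    """Hashed character-trigram embedding.

    A coarser alternative backend used to check that G-match rankings are
    not an artifact of exact word overlap: units are represented by counts
    of character 3-grams of their joined text, hashed (MD5) into a fixed
    number of dimensions.
    """

    name = "trigram"
    deterministic = True

    def __init__(self, dim: int = 4096):
        self.dim = int(dim)

    def embed(self, units: Sequence[Sequence[str]]) -> np.ndarray:
        mat = np.zeros((len(units), self.dim), dtype=float)
        for i, unit in enumerate(units):
            text = " ".join(unit)
            for k in range(max(len(text) - 2, 0)):
                gram = text[k:k + 3]
                h = int.from_bytes(hashlib.md5(gram.encode()).digest()[:8], "big")
                mat[i, h % self.dim] += 1.0
        return _l2_normalize(mat)


_BACKENDS = {"counts": CountsBackend, "trigram": TrigramBackend}


def get_backend(name: str | EmbeddingBackend) -> EmbeddingBackend:
    """Resolve a backend by name ('counts', 'trigram') or pass through."""
    if not isinstance(name, str):
        return name
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise ValueError(f"unknown embedding backend {name!r}; "
                         f"available: {sorted(_BACKENDS)}") from None


def _l2_normalize(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return mat / norms


@dataclass(frozen=True)
class GmatchResult:
    """G-match score with the per-source-unit similarity profile."""

    gmatch: float
    per_unit_similarity: tuple[float, ...]
    unit_weights: tuple[int, ...]
    backend_name: str


def segment_units(
    text: str,
    window: int = 15,
    filler_lexicon: Iterable[str] = DEFAULT_FILLER_LEXICON,
    prefix: str = "u",
) -> list[TextUnit]:
    """Split text into normalized sentence units.

    Sentences are delimited by ``. ! ?``; each is normalized and empty
    units are dropped. Unpunctuated text (a single run with no sentence
    delimiter, common in ASR retellings) falls back to fixed token windows
    of ``window`` tokens. Raises ``ValueError`` if nothing remains after
    normalization.
    """
    pieces = [p for p in _SENTENCE_SPLIT.split(text) if p.strip()]
    units: list[TextUnit] = []
    if _SENTENCE_SPLIT.search(text):
        for i, piece in enumerate(pieces):
            toks = normalize_transcript(piece, filler_lexicon).tokens
            if toks:
                units.append(TextUnit(f"{prefix}{len(units):03d}", toks))
    else:
        toks = normalize_transcript(text, filler_lexicon).tokens
        if window < 1:
            raise ValueError("window must be >= 1")
        for start in range(0, len(toks), window):
            chunk = toks[start:start + window]
            units.append(TextUnit(f"{prefix}{len(units):03d}", chunk))
    if not units:
        raise ValueError("text has no tokens after normalization")
    return units


def embed_units(
    units: Sequence[TextUnit], backend: str | EmbeddingBackend = "counts"
) -> np.ndarray:
    """Embed units; one L2-normalized vector per unit."""
    backend = get_backend(backend)
    try:
        vecs = backend.embed([u.tokens for u in units])
    except Exception as exc:  # surface which backend broke
        raise RuntimeError(f"embedding backend {backend.name!r} failed: {exc}") from exc
    vecs = np.asarray(vecs, dtype=float)
    if vecs.shape[0] != len(units):
        raise RuntimeError(
            f"backend {backend.name!r} returned {vecs.shape[0]} vectors "
            f"for {len(units)} units")
    return vecs


def gmatch(
    source_text: str,
    retelling_text: str,
    backend: str | EmbeddingBackend = "counts",
    window: int = 15,
    filler_lexicon: Iterable[str] = DEFAULT_FILLER_LEXICON,
) -> GmatchResult:
    """Score a retelling against its source story.

    An empty (or punctuation-only) retelling is a recorded null response
    and scores 0; an empty source story is an error.
    """
    backend = get_backend(backend)
    src_units = segment_units(source_text, window, filler_lexicon, prefix="s")
    weights = np.array([u.weight for u in src_units], dtype=float)
    try:
        ret_units = segment_units(retelling_text, window, filler_lexicon, prefix="r")
    except ValueError:
        return GmatchResult(0.0, (0.0,) * len(src_units),
                            tuple(int(w) for w in weights), backend.name)
    all_vecs = embed_units(list(src_units) + list(ret_units), backend)
    src_vecs = all_vecs[: len(src_units)]
    ret_vecs = all_vecs[len(src_units):]
    cos = np.clip(src_vecs @ ret_vecs.T, -1.0, 1.0)
    # normalization round-off can leave a self-match at 1 - O(eps); snap so
    # that verbatim recall attains the scale's defined maximum exactly
    cos[cos > 1.0 - 1e-12] = 1.0
    best = cos.max(axis=1)
    score = float(np.clip(np.sum(weights * np.maximum(best, 0.0)) / weights.sum(),
                          0.0, 1.0))
    return GmatchResult(score, tuple(float(s) for s in best),
                        tuple(int(w) for w in weights), backend.name)


def score_dataset(
    stories: dict,
    transcripts,
    backend: str | EmbeddingBackend = "counts",
    window: int = 15,
    score_null_responses: bool = True,
) -> pd.DataFrame:
    """Score every retelling in a dataset and attach session triplet means.

    ``stories`` maps story_id to Story; ``transcripts`` is a sequence of
    TranscriptRecord (or a DataFrame with the same columns). An empty
    retelling text is a recorded null response: scored 0 when
    ``score_null_responses`` (the participant engaged and recalled
    nothing), or left missing otherwise. ``triplet_mean`` is the mean of
    available scores in the (participant, day, recall type) session.
    """
    backend = get_backend(backend)
    if not isinstance(transcripts, pd.DataFrame):
        import dataclasses

        transcripts = pd.DataFrame(
            [dataclasses.asdict(t) for t in transcripts])
    rows = []
    for rec in transcripts.itertuples(index=False):
        text = rec.text if isinstance(rec.text, str) else ""
        if not text.strip() and not score_null_responses:
            score = float("nan")
        else:
            score = gmatch(stories[rec.story_id].text, text, backend,
                           window).gmatch
        rows.append((rec.participant_id, int(rec.day), rec.story_id,
                     rec.recall_type, int(rec.order), score))
    scores = pd.DataFrame(rows, columns=["participant_id", "day", "story_id",
                                         "recall_type", "order", "gmatch"])
    scores["triplet_mean"] = scores.groupby(
        ["participant_id", "day", "recall_type"])["gmatch"].transform("mean")
    return scores


def triplet_mean(scores: Iterable[float]) -> float:
    """Mean G-match over the stories available in one session.

    Skipped stories simply do not contribute; a session with no scored
    story yields NaN (missing), never 0 — non-engagement is not poor
    recall.
    """
    vals = [s for s in scores if s is not None and not np.isnan(s)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))
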