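"""Per-message negative-sentiment probability and two-stage aggregation.

A :class:`SentimentScorer` maps a message to the probability of negative
polarity, ``p_neg`` in [0, 1] (binary contract: ``p_pos = 1 - p_neg``).
Aggregation follows the chat-as-unit design: message scores are averaged
within each chat, then chat means are averaged (unweighted) across the
chats of a group, with the SEM taken across chats. Pooling all messages
would weight big chats more; the two-stage rule does not.

The production adapter wraps a published Italian binary sentiment
transformer as an optional extra; the in-repo :func:`lexicon_stub_scorer`
is a deterministic test double fulfilling the same contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol

from .autocode import CodeMatrix
from .ingest import Corpus
from .stats import sem


class SentimentConfigError(ValueError):
    pass


class SentimentScorer(Protocol):
    def score(self, text: str) -> float: ...


@dataclass
class SentimentSummary:
    """Per-message, per-chat, and per-group negative-sentiment aggregates."""

    per_message: dict[tuple[str, int], float] = field(default_factory=dict)
    per_chat: dict[str, float] = field(default_factory=dict)
    per_group: dict[str, tuple[float, float | None]] = field(default_factory=dict)
    skipped: int = 0


def _aggregate(
    corpus: Corpus,
    messages_by_chat: dict[str, list[tuple[int, str]]],
    scorer: SentimentScorer,
) -> SentimentSummary:
    summary = SentimentSummary()
    chat_values: dict[str, list[float]] = {}
    for chat in corpus.chats:
        scores: list[float] = []
        for idx, text in messages_by_chat.get(chat.chat_id, []):
            if not text.strip():
                summary.skipped += 1
                continue
            try:
                p_neg = float(scorer.score(text))
            except Exception:
                summary.skipped += 1
                continue
            summary.per_message[(chat.chat_id, idx)] = p_neg
            scores.append(p_neg)
        if scores:
            summary.per_chat[chat.chat_id] = sum(scores) / len(scores)
            chat_values.setdefault(corpus.labels[chat.chat_id], []).append(
                summary.per_chat[chat.chat_id]
            )
    for label, values in chat_values.items():
        mean = sum(values) / len(values)
        summary.per_group[label] = (mean, sem(values) if len(values) >= 2 else None)
    return summary


def score_corpus(corpus: Corpus, scorer: SentimentScorer) -> SentimentSummary:
    """Score every textual message and aggregate chat-then-group.

    Messages left empty after privacy transformation, and messages the
    scorer fails on, are skipped (not default-scored) and counted.
    """
    by_chat = {
        chat.chat_id: [(i, m.text) for i, m in enumerate(chat.messages) if m.is_textual]
        for chat in corpus.chats
    }
    return _aggregate(corpus, by_chat, scorer)


def sentiment_by_code(
    corpus: Corpus, matrix: CodeMatrix, code: str, scorer: SentimentScorer
) -> SentimentSummary:
    """Same aggregation, restricted to messages on which a code fired.

    Chats where the code never fired contribute nothing to the group mean.
    """
    by_chat = {}
    any_fired = False
    for chat in corpus.chats:
        fired = matrix.fired_indices(chat.chat_id, code)
        entries = [
            (i, m.text) for i, m in enumerate(chat.messages) if m.is_textual and i in fired
        ]
        if entries:
            any_fired = True
        by_chat[chat.chat_id] = entries
    if not any_fired:
        warnings.warn(f"code {code!r} fired on no message; empty summary", stacklevel=2)
    return _aggregate(corpus, by_chat, scorer)


@dataclass(frozen=True)
class _LexiconScorer:
    neg: frozenset[str]
    pos: frozenset[str]

    def score(self, text: str) -> float:
        tokens = [t.lower() for t in text.split()]
        n_neg = sum(1 for t in tokens if t.strip(".,!?;:()[]\"'").lower() in self.neg)
        n_pos = sum(1 for t in tokens if t.strip(".,!?;:()[]\"'").lower() in self.pos)
        if n_neg + n_pos == 0:
            return 0.5
        return n_neg / (n_neg + n_pos)


def lexicon_stub_scorer(neg_lexicon: Iterable[str], pos_lexicon: Iterable[str]) -> SentimentScorer:
    """Deterministic scorer: p_neg = neg hits / (neg + pos hits); 0.5 if none."""
    neg = frozenset(w.lower() for w in neg_lexicon)
    pos = frozenset(w.lower() for w in pos_lexicon)
    if not neg or not pos:
        raise SentimentConfigError("both lexicons must be non-empty")
    if neg & pos:
        raise SentimentConfigError(f"lexicons overlap: {sorted(neg & pos)}")
    return _LexiconScorer(neg=neg, pos=pos)


class TransformerScorer:
    """Adapter over a binary Italian sentiment transformer (optional extra)."""

    def __init__(self, model: str = "MilaNLProc/feel-it-italian-sentiment"):
        try:  # pragma: no cover - optional extra
            from transformers import pipeline  # noqa: PLC0415
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "transformers is not installed; install the 'sentiment' extra"
            ) from exc
        self._pipe = pipeline("text-classification", model=model, top_k=None)  # pragma: no cover

    def score(self, text: str) -> float:  # pragma: no cover
        results = {r["label"].lower(): r["score"] for r in self._pipe(text)[0]}
        total = results.get("negative", 0.0) + results.get("positive", 0.0)
        if total <= 0 or not math.isfinite(total):
            raise ValueError("scorer returned no usable polarity scores")
        return results.get("negative", 0.0) / total


def get_scorer(name: str, neg_lexicon=None, pos_lexicon=None) -> SentimentScorer:
    if name == "stub":
        return lexicon_stub_scorer(neg_lexicon, pos_lexicon)
    if name == "transformer":
        return TransformerScorer()
    raise SentimentConfigError(f"unknown scorer {name!r}")
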