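"""Parsing of Telegram Desktop chat exports into a uniform in-memory corpus.

Telegram's desktop client ("export chat history") writes one ``result.json``
per chat with a top-level ``name``/``type``/``id`` and a ``messages`` array.
The ``text`` field of each entry is polymorphic: a plain string, or an array
mixing strings with typed entity objects (mentions, links, bold spans, ...).
Newer client versions additionally emit a ``text_entities`` array; when both
are present the entity array is authoritative.

Only textual content is retained; attachments contribute empty text.
Service entries (joins, pins, calls) are parsed but flagged so downstream
analytics can exclude them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Any, Iterable, Mapping


class ExportParseError(ValueError):
    """A chat export document could not be interpreted."""


class CorpusConfigError(ValueError):
    """Corpus-level configuration is inconsistent (e.g. unlabeled chats)."""


@dataclass(frozen=True)
class RawMessage:
    """One entry of a chat export, with its text already flattened."""

    msg_id: int
    timestamp: str  # ISO-8601, timezone-naive as exported
    sender_id: str | None
    sender_name: str | None
    kind: str  # "message" | "service"
    text: str

    @property
    def is_textual(self) -> bool:
        return self.kind == "message"

    def datetime(self) -> datetime:
        return datetime.fromisoformat(self.timestamp)


@dataclass
class RawExport:
    """A parsed chat export: chat metadata plus messages in export order."""

    chat_name: str
    chat_id: str
    chat_type: str  # group | supergroup | channel | other
    messages: list[RawMessage] = field(default_factory=list)

    @property
    def textual_messages(self) -> list[RawMessage]:
        return [m for m in self.messages if m.is_textual]


@dataclass
class Corpus:
    """A set of chats with exactly one group label per chat."""

    chats: list[RawExport]
    labels: dict[str, str]

    def chats_in_group(self, label: str) -> list[RawExport]:
        return [c for c in self.chats if self.labels[c.chat_id] == label]

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for chat in self.chats:
            lab = self.labels[chat.chat_id]
            if lab not in seen:
                seen.append(lab)
        return seen


_KNOWN_CHAT_TYPES = {
    "private_group": "group",
    "public_group": "group",
    "private_supergroup": "supergroup",
    "public_supergroup": "supergroup",
    "private_channel": "channel",
    "public_channel": "channel",
    "group": "group",
    "supergroup": "supergroup",
    "channel": "channel",
}


def flatten_text(text: Any) -> str:
    """Flatten Telegram's polymorphic text field to a plain string.

    Strings pass through unchanged (idempotent); arrays are concatenated in
    order, taking the ``text`` member of entity objects. Anything without
    textual content contributes the empty string.
    """
    if text is None:
        return ""
    if isinstance(text, str):
        return text
    if isinstance(text, list):
        parts: list[str] = []
        for piece in text:
            if isinstance(piece, str):
                parts.append(piece)
            elif isinstance(piece, Mapping):
                parts.append(str(piece.get("text", "")))
            else:
                parts.append(str(piece))
        return "".join(parts)
    return str(text)


def _parse_entry(entry: Mapping[str, Any], index: int) -> RawMessage:
    try:
        msg_id = int(entry["id"])
        timestamp = str(entry["date"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ExportParseError(f"malformed message entry at index {index}: {exc}") from exc

    kind = "service" if entry.get("type") == "service" else "message"
    # text_entities (newer exports) wins over the legacy polymorphic field
    if "text_entities" in entry:
        text = flatten_text(entry["text_entities"])
    else:
        text = flatten_text(entry.get("text"))

    sender_id = entry.get("from_id") or entry.get("actor_id")
    sender_name = entry.get("from") or entry.get("actor")
    return RawMessage(
        msg_id=msg_id,
        timestamp=timestamp,
        sender_id=str(sender_id) if sender_id is not None else None,
        sender_name=str(sender_name) if sender_name is not None else None,
        kind=kind,
        text=text,
    )


def parse_export(doc: Mapping[str, Any] | str | Path) -> RawExport:
    """Parse one export document (mapping, JSON string, or file path)."""
    if isinstance(doc, (str, Path)):
        path = Path(doc)
        if path.exists():
            doc = json.loads(path.read_text(encoding="utf-8"))
        else:
            doc = json.loads(str(doc))
    if not isinstance(doc, Mapping):
        raise ExportParseError("export document is not a JSON object")
    if "messages" not in doc or not isinstance(doc["messages"], list):
        raise ExportParseError("export document has no message list")

    messages = [_parse_entry(entry, i) for i, entry in enumerate(doc["messages"])]
    raw_type = str(doc.get("type", "other"))
    return RawExport(
        chat_name=str(doc.get("name", "")),
        chat_id=str(doc.get("id", doc.get("name", ""))),
        chat_type=_KNOWN_CHAT_TYPES.get(raw_type, "other"),
        messages=messages,
    )


def filter_eligible(
    chat: RawExport,
    reference_date: date,
    member_count: int,
    min_recent: int = 10,
    window_days: int = 7,
    min_members: int = 200,
) -> bool:
    """Apply the chat-eligibility screen: recent activity and group size.

    A chat qualifies when at least ``min_recent`` textual messages fall in
    the ``window_days`` days up to ``reference_date`` (inclusive bounds) and
    the externally supplied ``member_count`` is at least ``min_members``.
    Exports do not record membership, so the count must come from config.
    """
    if member_count < min_members:
        return False
    lo = reference_date - timedelta(days=window_days)
    recent = 0
    for msg in chat.messages:
        if msg.kind != "message":
            continue
        try:
            d = msg.datetime().date()
        except ValueError:
            continue
        if lo <= d <= reference_date:
            recent += 1
    return recent >= min_recent


def build_corpus(exports: Iterable[RawExport], labels: Mapping[str, str]) -> Corpus:
    """Assemble labelled chats into a Corpus; every chat must carry a label."""
    chats = list(exports)
    missing = [c.chat_id for c in chats if c.chat_id not in labels]
    if missing:
        raise CorpusConfigError(f"chats without a group label: {missing}")
    if not chats:
        warnings.warn("building an empty corpus", stacklevel=2)
    used = {c.chat_id: labels[c.chat_id] for c in chats}
    return Corpus(chats=chats, labels=used)


# ---------------------------------------------------------------------------
# internal corpus JSON (round-trips through the CLI between stages)

def corpus_to_json(corpus: Corpus) -> dict[str, Any]:
    return {
        "chats": [
            {
                "chat_name": c.chat_name,
                "chat_id": c.chat_id,
                "chat_type": c.chat_type,
                "messages": [
                    {
                        "msg_id": m.msg_id,
                        "timestamp": m.timestamp,
                        "sender_id": m.sender_id,
                        "sender_name": m.sender_name,
                        "kind": m.kind,
                        "text": m.text,
                    }
                    for m in c.messages
                ],
            }
            for c in corpus.chats
        ],
        "labels": dict(corpus.labels),
    }


def corpus_from_json(obj: Mapping[str, Any]) -> Corpus:
    chats = [
        RawExport(
            chat_name=c["chat_name"],
            chat_id=c["chat_id"],
            chat_type=c["chat_type"],
            messages=[RawMessage(**m) for m in c["messages"]],
        )
        for c in obj["chats"]
    ]
    return Corpus(chats=chats, labels=dict(obj["labels"]))


def copy_corpus(corpus: Corpus) -> Corpus:
    """Deep-ish copy so privacy transforms never touch the original."""
    return Corpus(
        chats=[
            RawExport(
                chat_name=c.chat_name,
                chat_id=c.chat_id,
                chat_type=c.chat_type,
                messages=[replace(m) for m in c.messages],
            )
            for c in corpus.chats
        ],
        labels=dict(corpus.labels),
    )
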