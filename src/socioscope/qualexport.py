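"""Structured, code-annotated export for qualitative thematic analysis.

Each message is rendered as a header line — ``«pseudonym» [code:weight,…]``
— followed by its text split on newlines. Quote positions in qualitative
write-ups refer to *text* lines of the subcorpus file, so headers are
excluded from the line numbering: the sidecar index maps every message to
its (start, end) text-line range, 1-based and contiguous, and
:func:`locate` inverts it for quote auditing. Re-export of the same inputs
is byte-identical (no timestamps in the body, stable ordering).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from .autocode import CodeMatrix
from .ingest import Corpus


class LocateError(LookupError):
    pass


@dataclass
class AnnotatedDocument:
    """An annotated subcorpus: rendered lines plus a message line index."""

    label: str
    lines: list[str] = field(default_factory=list)  # full render, headers included
    index: dict[tuple[str, int], tuple[int, int]] = field(default_factory=dict)

    def render(self) -> str:
        return "\n".join(self.lines) + ("\n" if self.lines else "")

    def index_json(self) -> dict:
        return {
            "label": self.label,
            "messages": [
                {"chat_id": cid, "msg_index": idx, "start_line": s, "end_line": e}
                for (cid, idx), (s, e) in sorted(self.index.items(), key=lambda kv: kv[1][0])
            ],
        }


def export_annotated(
    subset: Corpus,
    matrix: CodeMatrix | None,
    label: str,
) -> AnnotatedDocument:
    """Render an anonymized, coded subcorpus into an annotated document.

    Messages appear in corpus order (chats in corpus order, messages in
    export order). The index records each message's text-line range;
    header lines do not advance the text-line counter.
    """
    doc = AnnotatedDocument(label=label)
    text_line = 0
    for chat in subset.chats:
        for idx, msg in enumerate(chat.messages):
            if not msg.is_textual:
                continue
            codes = ""
            if matrix is not None:
                fired = [
                    f"{code}:{matrix.weight(chat.chat_id, idx, code)}"
                    for code in matrix.codes
                    if matrix.weight(chat.chat_id, idx, code) >= 1
                ]
                codes = f" [{','.join(fired)}]" if fired else ""
            speaker = msg.sender_id if msg.sender_id is not None else "user_unknown"
            doc.lines.append(f"«{speaker}»{codes}")
            body = msg.text.split("\n") if msg.text else [""]
            start = text_line + 1
            for line in body:
                doc.lines.append(line)
                text_line += 1
            doc.index[(chat.chat_id, idx)] = (start, text_line)
    return doc


def locate(doc: AnnotatedDocument, position: int | tuple[int, int]) -> tuple[str, int]:
    """Find the message whose text-line range contains a position.

    ``position`` is a 1-based text-line number or an inclusive (start, end)
    range; a range must fall within a single message.
    """
    if isinstance(position, tuple):
        start, end = position
    else:
        start = end = position
    if start < 1 or end < start:
        raise LocateError(f"invalid position {position!r} (text lines are 1-based)")
    for key, (s, e) in doc.index.items():
        if s <= start and end <= e:
            return key
    raise LocateError(f"position {position!r} is outside every message range")


def write_annotated(doc: AnnotatedDocument, text_path, index_path=None) -> None:
    with open(text_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(doc.render())
    if index_path is not None:
        with open(index_path, "w", encoding="utf-8") as fh:
            json.dump(doc.index_json(), fh, indent=1, ensure_ascii=False)
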