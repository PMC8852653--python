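"""Weighted regex-dictionary autocoding.

A *dictionary* is a named concept (code) represented by an ordered list of
regular expressions. A dictionary "fires" on a message when at least one of
its patterns matches; the message's weight for that code is the number of
distinct patterns that matched (repeated matches of one pattern count
once): one firing rule gives weight 1, two firing rules give weight 2, and
so on. Autocode weights measure the prevalence of a topic through the
corpus, segment the quantitative analyses, and seed the qualitative work.

Patterns are standard Python ``re`` syntax with Unicode word characters
(Italian diacritics count as ``\\w``). Matching is case-insensitive by
default since chat text is casually cased.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .ingest import Corpus


class DictionaryError(ValueError):
    pass


@dataclass(frozen=True)
class DictionarySpec:
    """A named set of regex rules describing one concept."""

    code: str
    patterns: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if not self.patterns:
            raise DictionaryError(f"dictionary {self.code!r} has no patterns")


@dataclass(frozen=True)
class CompiledDictionary:
    code: str
    matchers: tuple[re.Pattern, ...]
    spec: DictionarySpec

    def __len__(self) -> int:
        return len(self.matchers)


def compile_dictionary(spec: DictionarySpec, case_insensitive: bool = True) -> CompiledDictionary:
    """Compile a dictionary's patterns, preserving order.

    Raises :class:`DictionaryError` naming the code and the zero-based
    pattern index when a pattern does not compile.
    """
    flags = re.UNICODE | (re.IGNORECASE if case_insensitive else 0)
    matchers = []
    for i, pat in enumerate(spec.patterns):
        try:
            matchers.append(re.compile(pat, flags))
        except re.error as exc:
            raise DictionaryError(
                f"dictionary {spec.code!r}: pattern {i} ({pat!r}) does not compile: {exc}"
            ) from exc
    return CompiledDictionary(code=spec.code, matchers=tuple(matchers), spec=spec)


def compile_dictionaries(
    specs: Iterable[DictionarySpec], case_insensitive: bool = True
) -> list[CompiledDictionary]:
    """Compile a dictionary set, enforcing unique code labels."""
    specs = list(specs)
    seen: set[str] = set()
    for spec in specs:
        if spec.code in seen:
            raise DictionaryError(f"duplicate code label {spec.code!r} in dictionary set")
        seen.add(spec.code)
    return [compile_dictionary(s, case_insensitive) for s in specs]


def code_message(text: str, dictionary: CompiledDictionary, count_occurrences: bool = False) -> int:
    """Weight of one message for one code.

    Default semantics: the number of *distinct* patterns with at least one
    match. With ``count_occurrences`` every match occurrence is counted
    instead (an explicit alternative reading, off by default).
    """
    if count_occurrences:
        return sum(len(m.findall(text)) for m in dictionary.matchers)
    return sum(1 for m in dictionary.matchers if m.search(text) is not None)


@dataclass
class CodeMatrix:
    """Sparse (chat_id, msg_index, code) -> weight map; absent means 0."""

    weights: dict[tuple[str, int, str], int] = field(default_factory=dict)
    codes: tuple[str, ...] = ()

    def weight(self, chat_id: str, msg_index: int, code: str) -> int:
        return self.weights.get((chat_id, msg_index, code), 0)

    def fired_indices(self, chat_id: str, code: str) -> set[int]:
        return {
            idx for (cid, idx, c), w in self.weights.items() if cid == chat_id and c == code and w >= 1
        }

    def to_json(self) -> dict:
        return {
            "codes": list(self.codes),
            "weights": [
                {"chat_id": cid, "msg_index": idx, "code": c, "weight": w}
                for (cid, idx, c), w in sorted(self.weights.items())
            ],
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "CodeMatrix":
        weights = {
            (e["chat_id"], e["msg_index"], e["code"]): e["weight"] for e in obj["weights"]
        }
        return cls(weights=weights, codes=tuple(obj["codes"]))


def code_corpus(corpus: Corpus, dictionaries: Sequence[CompiledDictionary]) -> CodeMatrix:
    """Code every textual message of a corpus against every dictionary.

    Message indices refer to positions in each chat's full message list, so
    weights stay aligned with the corpus whatever the service-message
    layout. Deterministic by construction.
    """
    weights: dict[tuple[str, int, str], int] = {}
    for chat in corpus.chats:
        for idx, msg in enumerate(chat.messages):
            if not msg.is_textual:
                continue
            for d in dictionaries:
                w = code_message(msg.text, d)
                if w > 0:
                    weights[(chat.chat_id, idx, d.code)] = w
    return CodeMatrix(weights=weights, codes=tuple(d.code for d in dictionaries))


def rule_frequency(corpus: Corpus, matrix: CodeMatrix, code: str) -> dict[str, float]:
    """Per-chat firing prevalence of a code, in percent.

    For each chat: 100 x (textual messages with weight >= 1) / (textual
    messages). Chats with no textual messages are excluded with a warning.
    Result keys are chat_ids in sorted order.
    """
    out: dict[str, float] = {}
    for chat in sorted(corpus.chats, key=lambda c: c.chat_id):
        textual = [i for i, m in enumerate(chat.messages) if m.is_textual]
        if not textual:
            warnings.warn(f"chat {chat.chat_id} has no textual messages; excluded", stacklevel=2)
            continue
        fired = matrix.fired_indices(chat.chat_id, code)
        out[chat.chat_id] = 100.0 * len(fired.intersection(textual)) / len(textual)
    return out


def coverage_report(
    corpus: Corpus,
    dictionaries: Sequence[CompiledDictionary],
    sample_non_matching: int = 10,
) -> dict:
    """Per-pattern firing counts plus a sample of messages no code matched.

    Dictionary development is iterative — run, inspect the gaps, refine the
    expressions — and this report is the inspection surface.
    """
    per_pattern: dict[str, list[int]] = {d.code: [0] * len(d) for d in dictionaries}
    unmatched: list[str] = []
    for chat in corpus.chats:
        for msg in chat.messages:
            if not msg.is_textual:
                continue
            any_hit = False
            for d in dictionaries:
                for i, m in enumerate(d.matchers):
                    if m.search(msg.text):
                        per_pattern[d.code][i] += 1
                        any_hit = True
            if not any_hit and len(unmatched) < sample_non_matching and msg.text.strip():
                unmatched.append(msg.text)
    return {"per_pattern_hits": per_pattern, "unmatched_sample": unmatched}


def load_dictionaries(path: str | Path) -> list[DictionarySpec]:
    """Read a dictionary set from YAML (list of code/description/patterns)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise DictionaryError("dictionary file must contain a list of dictionaries")
    specs = []
    for entry in raw:
        specs.append(
            DictionarySpec(
                code=str(entry["code"]),
                patterns=tuple(str(p) for p in entry["patterns"]),
                description=str(entry.get("description", "")),
            )
        )
    return specs
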