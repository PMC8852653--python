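"""Anonymization and pseudonymization of chat corpora.

Identifying text is replaced irreversibly with placeholders — ``[username]``
for @-mentions, ``[name]`` for personal first names, ``[place]`` for
toponyms — while user identifiers are swapped for consistent pseudonyms so
conversations stay traceable without revealing identity. Surnames are
deliberately retained: in informal chats they refer to public figures and
information sources, not to chat members, and carry analytical value.

Scrub order is mentions -> names -> toponyms, so ``@marco`` becomes
``[username]`` rather than ``[name]``: mentions are structurally
identifiable and take precedence over lexicon hits.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, replace
from typing import Iterable

from .ingest import Corpus, copy_corpus

USERNAME_PLACEHOLDER = "[username]"
NAME_PLACEHOLDER = "[name]"
PLACE_PLACEHOLDER = "[place]"
PLACEHOLDERS = (USERNAME_PLACEHOLDER, NAME_PLACEHOLDER, PLACE_PLACEHOLDER)

# an @-handle needs a non-word character (or start of string) before the @,
# so e-mail-like strings such as "a@b" are left alone
_MENTION_RE = re.compile(r"(?<![\w.])@\w+")


class PrivacyConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ScrubLexicons:
    """Word lists driving name/toponym scrubbing (case-insensitive, whole-word)."""

    names: frozenset[str]
    toponyms: frozenset[str]

    @classmethod
    def from_iterables(cls, names: Iterable[str], toponyms: Iterable[str]) -> "ScrubLexicons":
        return cls(
            names=frozenset(n.strip().lower() for n in names if n.strip()),
            toponyms=frozenset(t.strip().lower() for t in toponyms if t.strip()),
        )

    @classmethod
    def from_files(cls, names_path, toponyms_path) -> "ScrubLexicons":
        def read(path):
            with open(path, encoding="utf-8") as fh:
                return [line.strip() for line in fh if line.strip()]

        return cls.from_iterables(read(names_path), read(toponyms_path))


@dataclass(frozen=True)
class PseudonymMap:
    """Deterministic bijection sender_id -> ``user_NNNN`` token.

    Tokens are assigned sequentially after a seeded shuffle of the sorted
    identifier set, so the mapping is reproducible for a fixed (id set,
    seed) yet unlinkable to insertion order.
    """

    mapping: dict[str, str]
    seed: int

    @classmethod
    def build(cls, sender_ids: Iterable[str], seed: int) -> "PseudonymMap":
        ids = sorted({s for s in sender_ids if s is not None})
        rng = random.Random(seed)
        rng.shuffle(ids)
        width = max(4, len(str(len(ids))))
        mapping = {sid: f"user_{i:0{width}d}" for i, sid in enumerate(ids, start=1)}
        return cls(mapping=mapping, seed=seed)

    def __getitem__(self, sender_id: str) -> str:
        return self.mapping[sender_id]


def scrub_mentions(text: str) -> str:
    """Replace every @-handle with ``[username]``."""
    return _MENTION_RE.sub(USERNAME_PLACEHOLDER, text)


def _lexicon_pattern(words: frozenset[str]) -> re.Pattern | None:
    if not words:
        return None
    alternation = "|".join(re.escape(w) for w in sorted(words, key=len, reverse=True))
    return re.compile(rf"\b(?:{alternation})\b", re.IGNORECASE)


def scrub_entities(text: str, lexicons: ScrubLexicons) -> str:
    """Replace lexicon names with ``[name]`` and toponyms with ``[place]``.

    Matching is whole-word and case-insensitive. Only listed first names are
    removed; surnames (absent from the lexicon) pass through untouched.
    """
    name_re = _lexicon_pattern(lexicons.names)
    place_re = _lexicon_pattern(lexicons.toponyms)
    if name_re is not None:
        text = name_re.sub(NAME_PLACEHOLDER, text)
    if place_re is not None:
        text = place_re.sub(PLACE_PLACEHOLDER, text)
    return text


def anonymize_corpus(
    corpus: Corpus,
    lexicons: ScrubLexicons,
    seed: int,
    scrub_names: bool = True,
) -> tuple[Corpus, PseudonymMap]:
    """Privacy-transform a corpus; the input object is left untouched.

    Every message text goes through mention scrubbing then lexicon
    scrubbing; sender ids are pseudonymized; display names and other
    non-essential metadata are dropped. Returns the transformed corpus and
    the pseudonym map (to be stored separately, or discarded).
    """
    if scrub_names and not (lexicons.names or lexicons.toponyms):
        raise PrivacyConfigError("scrubbing enabled but both lexicons are empty")

    all_senders = [
        m.sender_id for chat in corpus.chats for m in chat.messages if m.sender_id is not None
    ]
    pmap = PseudonymMap.build(all_senders, seed=seed)

    out = copy_corpus(corpus)
    for chat in out.chats:
        chat.messages = [
            replace(
                m,
                text=scrub_entities(scrub_mentions(m.text), lexicons)
                if scrub_names
                else scrub_mentions(m.text),
                sender_id=pmap[m.sender_id] if m.sender_id is not None else None,
                sender_name=None,
            )
            for m in chat.messages
        ]
    return out, pmap


def residual_identifiers(corpus: Corpus, lexicons: ScrubLexicons) -> list[str]:
    """Sweep a corpus for leftover handles/names/toponyms (empty == clean)."""
    name_re = _lexicon_pattern(lexicons.names)
    place_re = _lexicon_pattern(lexicons.toponyms)
    found: list[str] = []
    for chat in corpus.chats:
        for m in chat.messages:
            found.extend(_MENTION_RE.findall(m.text))
            if name_re is not None:
                found.extend(name_re.findall(m.text))
            if place_re is not None:
                found.extend(place_re.findall(m.text))
    return found
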