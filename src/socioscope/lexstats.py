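"""Lemma extraction and frequency analytics.

Lemma frequencies are computed on a bag of words over every message of a
(sub)corpus: tokens are lemmatized, function words (stoplist), punctuation,
numerals, URLs, and the privacy placeholders are dropped, and the retained
lemma counts are expressed as percentages of the retained total.

The :class:`Lemmatizer` contract is pluggable. The default in-repo
implementation is a deterministic lookup table (exact on the closed
synthetic vocabulary); :class:`SpacyLemmatizer` wraps a pretrained Italian
pipeline as an optional extra for real corpora.

Group-level reporting averages per-chat frequencies across the chats of a
group — matching error bars that show the SEM across chats — while pooled
whole-corpus frequencies are available separately and flagged as such.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

from .autocode import CodeMatrix
from .ingest import Corpus, RawExport
from .privacy import PLACEHOLDERS

# minimal Italian function-word stoplist (articles, prepositions, clitics,
# conjunctions, common adverbs); configurable per call
DEFAULT_STOPLIST = frozenset(
    """
    il lo la i gli le un uno una l un'
    di a da in con su per tra fra del dello della dei degli delle al allo
    alla ai agli alle dal dallo dalla dai dagli dalle nel nello nella nei
    negli nelle sul sullo sulla sui sugli sulle
    e o ma se anche pure come che chi cui non piu più già ancora sempre mai
    questo questa questi queste quello quella quelli quelle
    io tu lui lei noi voi loro mi ti si ci vi ne lo la li le
    essere avere
    """.split()
)

_TOKEN_RE = re.compile(r"\[(?:name|place|username)\]|https?://\S+|\w+", re.UNICODE)
_URL_RE = re.compile(r"https?://", re.IGNORECASE)

# part-of-speech tags excluded from frequency analysis
DEFAULT_DROP_POS = frozenset({"PUNCT", "NUM", "SYM", "SPACE", "X_URL"})


class Lemmatizer(Protocol):
    """Contract: map text to (surface, lemma, pos) triples in surface order."""

    def lemmas(self, text: str) -> list[tuple[str, str, str]]: ...


@dataclass(frozen=True)
class LookupLemmatizer:
    """Deterministic lemmatizer backed by a surface->(lemma, pos) table.

    Tokens outside the table are returned as their own lemma with tag
    "X". Tokenization is a simple Unicode word scan after case folding;
    purely numeric tokens are tagged NUM, URLs X_URL.
    """

    table: dict[str, tuple[str, str]] = field(default_factory=dict)

    def lemmas(self, text: str) -> list[tuple[str, str, str]]:
        out: list[tuple[str, str, str]] = []
        for tok in _TOKEN_RE.findall(text):
            if tok in PLACEHOLDERS:
                out.append((tok, tok, "PLACEHOLDER"))
                continue
            if _URL_RE.match(tok):
                out.append((tok, tok, "X_URL"))
                continue
            folded = tok.lower()
            if folded.isdigit():
                out.append((tok, folded, "NUM"))
                continue
            lemma, pos = self.table.get(folded, (folded, "X"))
            out.append((tok, lemma, pos))
        return out


class SpacyLemmatizer:
    """Adapter around a pretrained Italian pipeline (optional dependency)."""

    def __init__(self, model: str = "it_core_news_sm"):
        try:
            import spacy  # noqa: PLC0415
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "spaCy is not installed; install the 'nlp' extra and download "
                f"the {model} model to use this lemmatizer"
            ) from exc
        self._nlp = spacy.load(model, disable=["parser", "ner"])  # pragma: no cover

    def lemmas(self, text: str) -> list[tuple[str, str, str]]:  # pragma: no cover
        return [(t.text, t.lemma_.lower(), t.pos_) for t in self._nlp(text)]


@dataclass
class LemmaTable:
    """Lemma counts and percentage frequencies for one scope."""

    scope: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def freq_pct(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {}
        return {lemma: 100.0 * c / total for lemma, c in self.counts.items()}


def lemmatize_corpus(
    subset: Corpus | Sequence[RawExport],
    lemmatizer: Lemmatizer,
    stoplist: frozenset[str] | set[str] = DEFAULT_STOPLIST,
    drop_pos: frozenset[str] | set[str] = DEFAULT_DROP_POS,
) -> list[str]:
    """Concatenated retained-lemma stream over every textual message.

    Placeholders, stoplisted lemmas, and dropped part-of-speech classes
    (punctuation, numerals, symbols, URLs) are removed. Lemmas are
    case-folded and NFC-normalized before comparison.
    """
    chats = subset.chats if isinstance(subset, Corpus) else list(subset)
    stream: list[str] = []
    for chat in chats:
        stream.extend(_chat_stream(chat, lemmatizer, stoplist, drop_pos))
    if not stream:
        warnings.warn("lemmatization produced an empty token stream", stacklevel=2)
    return stream


def _chat_stream(chat: RawExport, lemmatizer, stoplist, drop_pos) -> list[str]:
    stream: list[str] = []
    for msg in chat.messages:
        if not msg.is_textual or not msg.text:
            continue
        for _surface, lemma, pos in lemmatizer.lemmas(msg.text):
            if pos == "PLACEHOLDER" or pos in drop_pos:
                continue
            lemma = unicodedata.normalize("NFC", lemma.lower())
            if lemma in stoplist:
                continue
            stream.append(lemma)
    return stream


def lemma_table(stream: Iterable[str], scope: str = "corpus") -> LemmaTable:
    """Count a lemma stream into a frequency table (freq_pct sums to 100)."""
    return LemmaTable(scope=scope, counts=dict(Counter(stream)))


def per_chat_lemma_frequency(
    corpus: Corpus,
    lemmatizer: Lemmatizer,
    lemma_set: str | Iterable[str],
    stoplist: frozenset[str] | set[str] = DEFAULT_STOPLIST,
    drop_pos: frozenset[str] | set[str] = DEFAULT_DROP_POS,
) -> dict[str, float]:
    """Summed freq_pct of a lemma set, computed on each chat's own stream.

    Chats whose stream comes out empty are excluded with a warning.
    """
    if isinstance(lemma_set, str):
        lemma_set = {lemma_set}
    lemma_set = set(lemma_set)
    if not lemma_set:
        raise ValueError("lemma set must be non-empty")
    out: dict[str, float] = {}
    for chat in sorted(corpus.chats, key=lambda c: c.chat_id):
        stream = _chat_stream(chat, lemmatizer, stoplist, drop_pos)
        if not stream:
            warnings.warn(f"chat {chat.chat_id}: empty lemma stream; excluded", stacklevel=2)
            continue
        table = lemma_table(stream, scope=chat.chat_id)
        out[chat.chat_id] = sum(table.freq_pct.get(lemma, 0.0) for lemma in lemma_set)
    return out


def subcorpus_by_code(corpus: Corpus, matrix: CodeMatrix, code: str) -> Corpus:
    """Restrict a corpus to the messages on which a code fired.

    Chat structure and message order are preserved; chats where the code
    never fired become empty (kept so chat-level scopes stay aligned).
    """
    if code not in matrix.codes:
        warnings.warn(f"code {code!r} absent from matrix; empty subcorpus", stacklevel=2)
    chats = []
    for chat in corpus.chats:
        fired = matrix.fired_indices(chat.chat_id, code)
        chats.append(
            RawExport(
                chat_name=chat.chat_name,
                chat_id=chat.chat_id,
                chat_type=chat.chat_type,
                messages=[m for i, m in enumerate(chat.messages) if i in fired],
            )
        )
    return Corpus(chats=chats, labels=dict(corpus.labels))


def top_lemmas(table: LemmaTable, n: int = 20) -> list[str]:
    """The n most frequent lemmas, ties broken lexicographically."""
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [lemma for lemma, _ in ranked[: max(n, 0)]]


def write_lemma_tsv(table: LemmaTable, path) -> None:
    freq = table.freq_pct
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lemma\tcount\tfreq_pct\n")
        for lemma in top_lemmas(table, n=len(table.counts)):
            fh.write(f"{lemma}\t{table.counts[lemma]}\t{freq[lemma]:.6f}\n")
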