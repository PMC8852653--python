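"""Synthetic Telegram-export corpora with planted, recoverable structure.

The study's chat data cannot be redistributed, so every pipeline stage is
exercised on generated corpora whose statistical structure is known in
closed form:

* messages are bags of filler tokens drawn i.i.d. from a multinomial over
  a closed vocabulary with a known surface->lemma map, so the lookup
  lemmatizer is exact (realism is deliberately sacrificed for
  verifiability);
* each message carries one sentiment token, negative with a per-group
  probability, so the lexicon stub scorer recovers the planted polarity
  mixture;
* dictionary-matching phrases are inserted per message with per-group
  probabilities, so per-chat rule frequencies are Bernoulli rates;
* planted names, @-mentions, and toponyms come from the scrub lexicons,
  making the privacy sweep assertion exact.

The default spec mirrors the study's design in miniature: 4 green-pass
opposition chats (3 "university" + 1 "generic") versus 4 control chats.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Any, Mapping

from scipy.stats import binom

from .autocode import CompiledDictionary, DictionarySpec, compile_dictionaries

OPPOSITION = "opposition"
CONTROL = "control"

# closed filler vocabulary: lemma -> (relative weight, surface forms);
# surfaces are chosen to hit no dictionary pattern, scrub lexicon, or
# sentiment lexicon
FILLER_VOCAB: dict[str, tuple[float, tuple[str, ...]]] = {
    "legge": (8.0, ("legge", "leggi")),
    "articolo": (6.0, ("articolo", "articoli")),
    "potere": (10.0, ("posso", "puoi", "possiamo")),
    "dovere": (9.0, ("devo", "devi", "dobbiamo")),
    "volere": (7.0, ("voglio", "vuoi", "vogliamo")),
    "sapere": (6.0, ("sappiamo", "sanno")),
    "chiedere": (5.0, ("chiedo", "chiedono")),
    "fare": (10.0, ("faccio", "fanno", "facciamo")),
    "dire": (8.0, ("dico", "dicono")),
    "parlare": (5.0, ("parlo", "parlano")),
    "prendere": (4.0, ("prendo", "prendono")),
    "mettere": (4.0, ("metto", "mettono")),
    "andare": (6.0, ("vado", "vanno", "andiamo")),
    "venire": (3.0, ("vengo", "vengono")),
    "scrivere": (3.0, ("scrivo", "scrivono")),
    "lavoro": (5.0, ("lavoro", "lavori")),
    "giorno": (5.0, ("giorno", "giorni")),
    "persona": (5.0, ("persona", "persone")),
    "gruppo": (4.0, ("gruppo", "gruppi")),
    "messaggio": (4.0, ("messaggio", "messaggi")),
    "domanda": (3.0, ("domanda", "domande")),
    "risposta": (3.0, ("risposta", "risposte")),
    "governo": (3.0, ("governo", "governi")),
    "regola": (3.0, ("regola", "regole")),
    "studente": (3.0, ("studente", "studenti")),
    "lezione": (2.0, ("lezione", "lezioni")),
    "treno": (2.0, ("treno", "treni")),
    "settimana": (2.0, ("settimana", "settimane")),
    "notizia": (2.0, ("notizia", "notizie")),
    "idea": (2.0, ("idea", "idee")),
}

NEG_LEXICON = ("paura", "rabbia", "vergogna", "schifo", "disastro", "assurdo")
POS_LEXICON = ("ottimo", "bello", "felice", "grazie", "fantastico", "bene")

NAME_LEXICON = ("marco", "giulia", "luca", "anna", "paolo", "chiara")
TOPONYM_LEXICON = ("milano", "roma", "torino", "napoli", "bologna")
HANDLES = ("@mariorossi", "@chat_admin", "@infokanale", "@thisuser")

GREEN_PASS_RULE = r"(tesser.\sverd.?|pass\sverd.?|certifica\w*\sverd.?)"

DEFAULT_DICTIONARIES = (
    DictionarySpec(
        code="green_pass",
        patterns=(GREEN_PASS_RULE,),
        description="COVID-19 certificate (green pass) concept",
    ),
    DictionarySpec(
        code="vaccine",
        patterns=(r"\bvaccin\w*",),
        description="vaccine concept",
    ),
)

DEFAULT_CODE_PHRASES: dict[str, tuple[str, ...]] = {
    "green_pass": ("tessera verde", "tessere verdi", "pass verde", "certificato verde"),
    "vaccine": ("vaccino", "vaccini", "vaccinazione"),
}

# surface -> (lemma, pos) covering fillers, phrase words, and sentiment words
def _build_lemma_map() -> dict[str, tuple[str, str]]:
    table: dict[str, tuple[str, str]] = {}
    for lemma, (_w, surfaces) in FILLER_VOCAB.items():
        for s in surfaces:
            table[s] = (lemma, "NOUN")
    for s, lemma in [
        ("tessera", "tessera"),
        ("tessere", "tessera"),
        ("verde", "verde"),
        ("verdi", "verde"),
        ("pass", "pass"),
        ("certificato", "certificato"),
        ("vaccino", "vaccino"),
        ("vaccini", "vaccino"),
        ("vaccinazione", "vaccinazione"),
    ]:
        table[s] = (lemma, "NOUN")
    for w in NEG_LEXICON + POS_LEXICON:
        table[w] = (w, "ADJ")
    return table


LEMMA_MAP: dict[str, tuple[str, str]] = _build_lemma_map()


class SpecValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Planted-truth parameters for the corpus generator."""

    groups: tuple[tuple[str, int, int], ...] = (
        (OPPOSITION, 4, 500),
        (CONTROL, 4, 500),
    )
    phrase_rates: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            (OPPOSITION, "green_pass"): 0.30,
            (CONTROL, "green_pass"): 0.05,
            (OPPOSITION, "vaccine"): 0.20,
            (CONTROL, "vaccine"): 0.08,
        }
    )
    lemma_distribution: Mapping[str, float] = field(
        default_factory=lambda: _normalized_filler_probs()
    )
    neg_word_rate: Mapping[str, float] = field(
        default_factory=lambda: {OPPOSITION: 0.6, CONTROL: 0.2}
    )
    n_users_per_chat: int = 12
    name_rate: float = 0.05
    mention_rate: float = 0.05
    toponym_rate: float = 0.05
    fillers_per_message: tuple[int, int] = (4, 8)  # inclusive range
    service_every: int = 100  # one service entry per this many messages
    entity_array_every: int = 10  # emit every k-th message as an entity array
    dictionaries: tuple[DictionarySpec, ...] = DEFAULT_DICTIONARIES
    code_phrases: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CODE_PHRASES)
    )
    seed: int = 7

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


def _normalized_filler_probs() -> dict[str, float]:
    total = sum(w for w, _s in FILLER_VOCAB.values())
    return {lemma: w / total for lemma, (w, _s) in FILLER_VOCAB.items()}


@dataclass(frozen=True)
class PlantedTruth:
    """Closed-form expectations implied by a SyntheticSpec."""

    rule_frequency_pct: Mapping[tuple[str, str], float]  # (label, code) -> %
    lemma_probs: Mapping[str, float]  # filler lemma -> conditional prob
    mean_p_neg: Mapping[str, float]  # label -> expected chat mean p_neg
    group_order_p_neg: tuple[str, ...]  # labels, most negative first


def validate_spec(spec: SyntheticSpec) -> list[CompiledDictionary]:
    """Check mutual consistency of vocabulary, lexicons, and phrases.

    Every planted phrase must match its own code's dictionary and no other
    code's; filler surfaces and sentiment words must match no dictionary.
    """
    dicts = compile_dictionaries(spec.dictionaries)
    by_code = {d.code: d for d in dicts}
    for code, phrases in spec.code_phrases.items():
        if code not in by_code:
            raise SpecValidationError(f"phrases given for unknown code {code!r}")
        for phrase in phrases:
            hits = [d.code for d in dicts if any(m.search(phrase) for m in d.matchers)]
            if hits != [code]:
                raise SpecValidationError(
                    f"phrase {phrase!r} must match exactly the {code!r} dictionary, matched {hits}"
                )
    neutral = [s for _l, (_w, surfaces) in FILLER_VOCAB.items() for s in surfaces]
    neutral += list(NEG_LEXICON) + list(POS_LEXICON)
    for word in neutral:
        for d in dicts:
            if any(m.search(word) for m in d.matchers):
                raise SpecValidationError(f"neutral token {word!r} matches dictionary {d.code!r}")
    for prob_map in (dict(spec.phrase_rates), dict(spec.neg_word_rate)):
        for key, p in prob_map.items():
            if not 0.0 <= p <= 1.0:
                raise SpecValidationError(f"probability out of range for {key!r}: {p}")
    lemmas_unknown = set(spec.lemma_distribution) - set(FILLER_VOCAB)
    if lemmas_unknown:
        raise SpecValidationError(f"lemma distribution names unknown lemmas: {lemmas_unknown}")
    return dicts


def planted_truth(spec: SyntheticSpec) -> PlantedTruth:
    total = sum(spec.lemma_distribution.values())
    probs = {l: p / total for l, p in spec.lemma_distribution.items()}
    order = tuple(sorted(spec.neg_word_rate, key=lambda lab: -spec.neg_word_rate[lab]))
    return PlantedTruth(
        rule_frequency_pct={k: 100.0 * v for k, v in spec.phrase_rates.items()},
        lemma_probs=probs,
        mean_p_neg=dict(spec.neg_word_rate),
        group_order_p_neg=order,
    )


def _chat_plan(spec: SyntheticSpec) -> list[tuple[str, str, str, int]]:
    """(label, chat_name, chat_id, n_messages) per chat, fixed order."""
    plan = []
    next_id = 1001
    opposition_names = ["university_north", "university_center", "university_south", "generic"]
    for label, n_chats, n_msgs in spec.groups:
        for k in range(n_chats):
            if label == OPPOSITION and k < len(opposition_names):
                name = opposition_names[k]
            else:
                name = f"{label}_{k + 1}"
            plan.append((label, name, str(next_id), n_msgs))
            next_id += 1
    return plan


def generate(spec: SyntheticSpec) -> tuple[list[dict[str, Any]], PlantedTruth]:
    """Generate one Telegram-style export document per chat, plus the truth.

    Documents are structurally valid for the ingest parser, including a
    fraction of entity-array texts and interleaved service entries.
    Byte-identical for a fixed spec (serialize with sorted keys to check).
    """
    validate_spec(spec)
    truth = planted_truth(spec)
    rng = random.Random(spec.seed)

    lemma_names = list(spec.lemma_distribution.keys())
    lemma_weights = [spec.lemma_distribution[l] for l in lemma_names]
    base_time = datetime(2021, 9, 15, 10, 0, 0)

    docs: list[dict[str, Any]] = []
    for label, chat_name, chat_id, n_msgs in _chat_plan(spec):
        users = [f"user{int(chat_id) * 1000 + u}" for u in range(spec.n_users_per_chat)]
        display = [f"Member {u}" for u in range(spec.n_users_per_chat)]
        entries: list[dict[str, Any]] = []
        msg_id = 1
        for i in range(n_msgs):
            if spec.service_every and i > 0 and i % spec.service_every == 0:
                entries.append(
                    {
                        "id": msg_id,
                        "type": "service",
                        "date": (base_time + timedelta(minutes=len(entries) * 3)).isoformat(),
                        "actor": "group admin",
                        "actor_id": users[0],
                        "action": "pin_message",
                        "text": "",
                    }
                )
                msg_id += 1
            u = rng.randrange(spec.n_users_per_chat)
            chunks: list[str] = []
            n_filler = rng.randint(*spec.fillers_per_message)
            chunks.extend(
                surface_for(lemma, rng)
                for lemma in rng.choices(lemma_names, weights=lemma_weights, k=n_filler)
            )
            if rng.random() < spec.neg_word_rate.get(label, 0.0):
                chunks.append(rng.choice(NEG_LEXICON))
            else:
                chunks.append(rng.choice(POS_LEXICON))
            for code, phrases in spec.code_phrases.items():
                if rng.random() < dict(spec.phrase_rates).get((label, code), 0.0):
                    chunks.append(rng.choice(phrases))
            if rng.random() < spec.name_rate:
                chunks.append(rng.choice(NAME_LEXICON).capitalize())
            if rng.random() < spec.toponym_rate:
                chunks.append(rng.choice(TOPONYM_LEXICON).capitalize())
            mention = rng.choice(HANDLES) if rng.random() < spec.mention_rate else None
            rng.shuffle(chunks)
            plain = " ".join(chunks)
            entry: dict[str, Any] = {
                "id": msg_id,
                "type": "message",
                "date": (base_time + timedelta(minutes=len(entries) * 3)).isoformat(),
                "from": display[u],
                "from_id": users[u],
            }
            if mention is not None:
                entry["text"] = [plain + " ", {"type": "mention", "text": mention}]
            elif spec.entity_array_every and i % spec.entity_array_every == 0:
                entry["text_entities"] = [{"type": "plain", "text": plain}]
                entry["text"] = plain
            else:
                entry["text"] = plain
            entries.append(entry)
            msg_id += 1
        docs.append(
            {
                "name": chat_name,
                "type": "private_supergroup",
                "id": int(chat_id),
                "messages": entries,
            }
        )
    return docs, truth


def surface_for(lemma: str, rng: random.Random) -> str:
    return rng.choice(FILLER_VOCAB[lemma][1])


def labels_for(spec: SyntheticSpec) -> dict[str, str]:
    """chat_id -> group label map matching :func:`generate` output."""
    return {chat_id: label for label, _name, chat_id, _n in _chat_plan(spec)}


def write_exports(docs: list[dict[str, Any]], out_dir) -> list[str]:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for doc in docs:
        path = out / f"{doc['name']}.json"
        path.write_text(
            json.dumps(doc, ensure_ascii=False, sort_keys=True, indent=1), encoding="utf-8"
        )
        paths.append(str(path))
    return paths


# ---------------------------------------------------------------------------
# recovery checking


def binomial_band(n: int, p: float, level: float = 0.95) -> tuple[int, int]:
    """Exact central binomial acceptance region for a count out of n."""
    alpha = 1.0 - level
    lo = int(binom.ppf(alpha / 2, n, p))
    hi = int(binom.ppf(1 - alpha / 2, n, p))
    return lo, hi


def recovery_report(
    truth: PlantedTruth,
    rule_fired: Mapping[tuple[str, str], tuple[int, int]] | None = None,
    lemma_counts: Mapping[str, Mapping[str, int]] | None = None,
    sentiment_neg: Mapping[str, tuple[int, int]] | None = None,
    level: float = 0.95,
) -> dict[str, dict]:
    """Compare recovered pipeline outputs against the planted truth.

    ``rule_fired``: (label, code) -> (messages fired, textual messages);
    ``lemma_counts``: label -> counts over *filler* lemmas only (counts are
    conditionally binomial given the filler total, so the exact band
    applies); ``sentiment_neg``: label -> (messages scored negative,
    messages scored). Quantities with missing outputs are marked untested.
    """
    report: dict[str, dict] = {}
    if rule_fired is not None:
        for (label, code), (k, n) in rule_fired.items():
            p = truth.rule_frequency_pct[(label, code)] / 100.0
            lo, hi = binomial_band(n, p, level)
            report[f"rule_frequency/{label}/{code}"] = {
                "planted": 100.0 * p,
                "recovered": 100.0 * k / n if n else float("nan"),
                "in_ci": bool(lo <= k <= hi),
            }
    else:
        report["rule_frequency"] = {"untested": True}
    if lemma_counts is not None:
        for label, counts in lemma_counts.items():
            total = sum(counts.get(l, 0) for l in truth.lemma_probs)
            for lemma, p in truth.lemma_probs.items():
                k = counts.get(lemma, 0)
                lo, hi = binomial_band(total, p, level)
                report[f"lemma_freq/{label}/{lemma}"] = {
                    "planted": 100.0 * p,
                    "recovered": 100.0 * k / total if total else float("nan"),
                    "in_ci": bool(lo <= k <= hi),
                }
    else:
        report["lemma_freq"] = {"untested": True}
    if sentiment_neg is not None:
        for label, (k, n) in sentiment_neg.items():
            p = truth.mean_p_neg[label]
            lo, hi = binomial_band(n, p, level)
            report[f"mean_p_neg/{label}"] = {
                "planted": p,
                "recovered": k / n if n else float("nan"),
                "in_ci": bool(lo <= k <= hi),
            }
    else:
        report["mean_p_neg"] = {"untested": True}
    return report
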