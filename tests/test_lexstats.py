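"""Lemma streams, frequency tables, and code-defined subcorpora."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from socioscope import autocode, ingest, lexstats, synthetic

STUB = lexstats.LookupLemmatizer(
    {
        "tessere": ("tessera", "NOUN"),
        "verdi": ("verde", "ADJ"),
        "va": ("andare", "VERB"),
        "green": ("green", "NOUN"),
        "pass": ("pass", "NOUN"),
    }
)


def _corpus_of(texts, chat_id="c1"):
    msgs = [
        ingest.RawMessage(i, "2021-09-01T10:00:00", "u1", None, "message", t)
        for i, t in enumerate(texts)
    ]
    return ingest.Corpus(
        [ingest.RawExport("chat", chat_id, "supergroup", msgs)], {chat_id: "g"}
    )


class TestLemmatize:
    def test_lookup_stub_maps_surface_forms(self):
        stream = lexstats.lemmatize_corpus(_corpus_of(["tessere verdi"]), STUB, stoplist=frozenset())
        assert stream == ["tessera", "verde"]

    def test_placeholders_and_stoplist_removed(self):
        stream = lexstats.lemmatize_corpus(
            _corpus_of(["[name] va a [place]"]), STUB, stoplist=frozenset({"a"})
        )
        assert stream == ["andare"]

    def test_numbers_and_urls_dropped(self):
        stream = lexstats.lemmatize_corpus(
            _corpus_of(["123 https://t.me/x tessere"]), STUB, stoplist=frozenset()
        )
        assert stream == ["tessera"]

    def test_deterministic(self, anon_corpus, stub_lemmatizer):
        s1 = lexstats.lemmatize_corpus(anon_corpus, stub_lemmatizer)
        s2 = lexstats.lemmatize_corpus(anon_corpus, stub_lemmatizer)
        assert s1 == s2

    def test_empty_subset_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert lexstats.lemmatize_corpus(_corpus_of([]), STUB) == []


class TestLemmaTable:
    def test_direct_ratio(self):
        stream = ["verde"] * 2 + ["x"] * 8
        table = lexstats.lemma_table(stream)
        assert table.freq_pct["verde"] == pytest.approx(20.0)

    def test_single_token_is_hundred_percent(self):
        assert lexstats.lemma_table(["solo"]).freq_pct == {"solo": 100.0}

    @given(st.lists(st.sampled_from("abcde"), min_size=1, max_size=200))
    def test_conservation_and_proportionality(self, stream):
        table = lexstats.lemma_table(stream)
        assert sum(table.freq_pct.values()) == pytest.approx(100.0, abs=1e-9)
        total = table.total
        for lemma, pct in table.freq_pct.items():
            assert pct == pytest.approx(100.0 * table.counts[lemma] / total)

    def test_corpus_counts_equal_sum_of_chat_counts(self, anon_corpus, stub_lemmatizer):
        whole = lexstats.lemma_table(lexstats.lemmatize_corpus(anon_corpus, stub_lemmatizer))
        summed: dict[str, int] = {}
        for chat in anon_corpus.chats:
            sub = ingest.Corpus([chat], {chat.chat_id: anon_corpus.labels[chat.chat_id]})
            for lemma, c in lexstats.lemma_table(
                lexstats.lemmatize_corpus(sub, stub_lemmatizer)
            ).counts.items():
                summed[lemma] = summed.get(lemma, 0) + c
        assert whole.counts == summed


class TestPerChatLemmaFrequency:
    def test_summed_set_frequency(self):
        corpus = _corpus_of(["green pass", "green x"])
        freq = lexstats.per_chat_lemma_frequency(corpus, STUB, {"green", "pass"}, stoplist=frozenset())
        assert freq == {"c1": pytest.approx(75.0)}

    def test_disjoint_set_gives_zero(self):
        corpus = _corpus_of(["green pass"])
        freq = lexstats.per_chat_lemma_frequency(corpus, STUB, {"assente"}, stoplist=frozenset())
        assert freq == {"c1": 0.0}

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            lexstats.per_chat_lemma_frequency(_corpus_of(["x"]), STUB, set())

    def test_recovers_planted_per_chat_rates(self):
        """Chats with planted lemma rates 0.10 / 0.30 are told apart."""
        import random

        rng = random.Random(0)
        texts_by_rate = {}
        for rate in (0.10, 0.30):
            texts_by_rate[rate] = [
                " ".join("green" if rng.random() < rate else "altro" for _ in range(40))
                for _ in range(50)
            ]
        chats = []
        for i, rate in enumerate((0.10, 0.30)):
            msgs = [
                ingest.RawMessage(j, "2021-09-01T10:00:00", "u", None, "message", t)
                for j, t in enumerate(texts_by_rate[rate])
            ]
            chats.append(ingest.RawExport(f"chat{i}", f"c{i}", "supergroup", msgs))
        corpus = ingest.Corpus(chats, {"c0": "g", "c1": "g"})
        freq = lexstats.per_chat_lemma_frequency(corpus, STUB, {"green"}, stoplist=frozenset())
        assert freq["c0"] == pytest.approx(10.0, abs=2.5)
        assert freq["c1"] == pytest.approx(30.0, abs=2.5)


class TestSubcorpusByCode:
    GP = autocode.compile_dictionary(
        autocode.DictionarySpec(code="green_pass", patterns=(synthetic.GREEN_PASS_RULE,))
    )

    def test_fired_messages_in_original_order(self):
        corpus = _corpus_of(["pass verde", "a", "tessere verdi", "b", "c"])
        matrix = autocode.code_corpus(corpus, [self.GP])
        sub = lexstats.subcorpus_by_code(corpus, matrix, "green_pass")
        assert [m.text for m in sub.chats[0].messages] == ["pass verde", "tessere verdi"]

    def test_code_firing_nowhere_gives_empty_subset(self):
        corpus = _corpus_of(["a", "b"])
        matrix = autocode.code_corpus(corpus, [self.GP])
        sub = lexstats.subcorpus_by_code(corpus, matrix, "green_pass")
        assert sub.chats[0].messages == []

    def test_idempotent(self):
        corpus = _corpus_of(["pass verde", "a", "tessere verdi"])
        matrix = autocode.code_corpus(corpus, [self.GP])
        sub = lexstats.subcorpus_by_code(corpus, matrix, "green_pass")
        matrix2 = autocode.code_corpus(sub, [self.GP])
        sub2 = lexstats.subcorpus_by_code(sub, matrix2, "green_pass")
        assert [m.text for m in sub2.chats[0].messages] == [
            m.text for m in sub.chats[0].messages
        ]

    def test_unknown_code_warns(self):
        corpus = _corpus_of(["a"])
        matrix = autocode.code_corpus(corpus, [self.GP])
        with pytest.warns(UserWarning, match="absent"):
            sub = lexstats.subcorpus_by_code(corpus, matrix, "missing")
        assert sub.chats[0].messages == []

    def test_subcorpus_enriched_for_phrase_lemmas(self, anon_corpus, stub_lemmatizer, small_spec):
        """Messages where the code fired over-represent the phrase lemmas."""
        dicts = autocode.compile_dictionaries(small_spec.dictionaries)
        matrix = autocode.code_corpus(anon_corpus, dicts)
        sub = lexstats.subcorpus_by_code(anon_corpus, matrix, "green_pass")
        whole = lexstats.lemma_table(lexstats.lemmatize_corpus(anon_corpus, stub_lemmatizer))
        coded = lexstats.lemma_table(lexstats.lemmatize_corpus(sub, stub_lemmatizer))
        for lemma in ("verde",):
            assert coded.freq_pct[lemma] > whole.freq_pct[lemma]


class TestTopLemmas:
    def test_descending_order(self):
        table = lexstats.LemmaTable("s", {"a": 50, "b": 30, "c": 20})
        assert lexstats.top_lemmas(table, 2) == ["a", "b"]

    def test_ties_broken_lexicographically(self):
        table = lexstats.LemmaTable("s", {"b": 40, "a": 40, "c": 10})
        assert lexstats.top_lemmas(table, 2) == ["a", "b"]

    def test_n_zero_and_n_beyond_vocabulary(self):
        table = lexstats.LemmaTable("s", {"a": 1, "b": 2})
        assert lexstats.top_lemmas(table, 0) == []
        assert lexstats.top_lemmas(table, 10) == ["b", "a"]
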