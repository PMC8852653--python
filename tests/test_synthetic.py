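"""The corpus generator: structure, determinism, and planted-truth recovery."""

import dataclasses
import json

import pytest

from socioscope import autocode, ingest, lexstats, privacy, sentiment, synthetic


class TestGenerate:
    def test_structural_shape(self, small_spec):
        docs, _truth = synthetic.generate(small_spec)
        assert len(docs) == 4
        for doc in docs:
            textual = [m for m in doc["messages"] if m["type"] == "message"]
            service = [m for m in doc["messages"] if m["type"] == "service"]
            assert len(textual) == 120
            assert service  # interleaved service entries present
        assert any(
            isinstance(m.get("text"), list) for doc in docs for m in doc["messages"]
        )

    def test_byte_identical_for_fixed_seed(self, small_spec):
        d1, _ = synthetic.generate(small_spec)
        d2, _ = synthetic.generate(small_spec)
        assert json.dumps(d1, sort_keys=True) == json.dumps(d2, sort_keys=True)

    def test_different_seed_changes_output(self, small_spec):
        d1, _ = synthetic.generate(small_spec)
        d2, _ = synthetic.generate(small_spec.with_seed(999))
        assert json.dumps(d1, sort_keys=True) != json.dumps(d2, sort_keys=True)

    def test_zero_phrase_rate_never_fires(self, small_spec):
        spec = dataclasses.replace(
            small_spec,
            phrase_rates={
                ("opposition", "green_pass"): 0.0,
                ("control", "green_pass"): 0.0,
                ("opposition", "vaccine"): 0.0,
                ("control", "vaccine"): 0.0,
            },
        )
        docs, _ = synthetic.generate(spec)
        corpus = ingest.build_corpus(
            [ingest.parse_export(d) for d in docs], synthetic.labels_for(spec)
        )
        dicts = autocode.compile_dictionaries(spec.dictionaries)
        matrix = autocode.code_corpus(corpus, dicts)
        assert matrix.weights == {}

    def test_inconsistent_phrase_rejected_before_generation(self, small_spec):
        spec = dataclasses.replace(
            small_spec, code_phrases={"green_pass": ("casa verde",)}
        )
        with pytest.raises(synthetic.SpecValidationError, match="casa verde"):
            synthetic.generate(spec)

    def test_probabilities_validated(self, small_spec):
        spec = dataclasses.replace(small_spec, neg_word_rate={"opposition": 1.4, "control": 0.2})
        with pytest.raises(synthetic.SpecValidationError):
            synthetic.generate(spec)


class TestPipelineSmoke:
    def test_all_stages_run_without_errors(self, small_spec, stub_lemmatizer, stub_scorer):
        docs, _truth = synthetic.generate(small_spec)
        corpus = ingest.build_corpus(
            [ingest.parse_export(d) for d in docs], synthetic.labels_for(small_spec)
        )
        lex = privacy.ScrubLexicons.from_iterables(
            synthetic.NAME_LEXICON, synthetic.TOPONYM_LEXICON
        )
        anon, _ = privacy.anonymize_corpus(corpus, lex, seed=3)
        assert privacy.residual_identifiers(anon, lex) == []
        dicts = autocode.compile_dictionaries(small_spec.dictionaries)
        matrix = autocode.code_corpus(anon, dicts)
        freq = autocode.rule_frequency(anon, matrix, "green_pass")
        assert len(freq) == 4
        table = lexstats.lemma_table(lexstats.lemmatize_corpus(anon, stub_lemmatizer))
        assert sum(table.freq_pct.values()) == pytest.approx(100.0, abs=1e-9)
        summary = sentiment.score_corpus(anon, stub_scorer)
        assert set(summary.per_group) == {"opposition", "control"}


def _recover(spec, stub_lemmatizer, stub_scorer):
    """Run the pipeline on a generated corpus and tally recovered counts."""
    docs, truth = synthetic.generate(spec)
    corpus = ingest.build_corpus(
        [ingest.parse_export(d) for d in docs], synthetic.labels_for(spec)
    )
    lex = privacy.ScrubLexicons.from_iterables(synthetic.NAME_LEXICON, synthetic.TOPONYM_LEXICON)
    anon, _ = privacy.anonymize_corpus(corpus, lex, seed=spec.seed)
    dicts = autocode.compile_dictionaries(spec.dictionaries)
    matrix = autocode.code_corpus(anon, dicts)

    rule_fired = {}
    for label, _n_chats, _n in spec.groups:
        chats = anon.chats_in_group(label)
        for code in matrix.codes:
            k = sum(len(matrix.fired_indices(c.chat_id, code)) for c in chats)
            n = sum(len(c.textual_messages) for c in chats)
            rule_fired[(label, code)] = (k, n)

    lemma_counts = {}
    for label, _n_chats, _n in spec.groups:
        sub = ingest.Corpus(
            anon.chats_in_group(label),
            {c.chat_id: label for c in anon.chats_in_group(label)},
        )
        lemma_counts[label] = lexstats.lemma_table(
            lexstats.lemmatize_corpus(sub, stub_lemmatizer, stoplist=frozenset())
        ).counts

    summary = sentiment.score_corpus(anon, stub_scorer)
    sentiment_neg = {}
    for label, _n_chats, _n in spec.groups:
        ids = {c.chat_id for c in anon.chats_in_group(label)}
        scores = [p for (cid, _i), p in summary.per_message.items() if cid in ids]
        sentiment_neg[label] = (sum(1 for p in scores if p > 0.5), len(scores))
    return truth, rule_fired, lemma_counts, sentiment_neg, summary


class TestRecovery:
    def test_planted_rates_recovered_within_binomial_bands(
        self, stub_lemmatizer, stub_scorer
    ):
        spec = synthetic.SyntheticSpec(
            groups=(("opposition", 2, 250), ("control", 2, 250)), seed=314
        )
        truth, rule_fired, lemma_counts, sentiment_neg, _ = _recover(
            spec, stub_lemmatizer, stub_scorer
        )
        report = synthetic.recovery_report(
            truth, rule_fired=rule_fired, lemma_counts=lemma_counts, sentiment_neg=sentiment_neg
        )
        checked = [q for q in report.values() if "in_ci" in q]
        assert checked
        frac = sum(q["in_ci"] for q in checked) / len(checked)
        assert frac >= 0.93

    def test_joint_coverage_across_seeds(self, stub_lemmatizer, stub_scorer):
        """At least 93% of planted quantities land in their 95% bands."""
        in_ci = total = 0
        for seed in range(20):
            spec = synthetic.SyntheticSpec(
                groups=(("opposition", 2, 120), ("control", 2, 120)), seed=1000 + seed
            )
            truth, rule_fired, _lemmas, sentiment_neg, _ = _recover(
                spec, stub_lemmatizer, stub_scorer
            )
            report = synthetic.recovery_report(
                truth, rule_fired=rule_fired, sentiment_neg=sentiment_neg
            )
            for q in report.values():
                if "in_ci" in q:
                    total += 1
                    in_ci += q["in_ci"]
        assert in_ci / total >= 0.93

    def test_missing_outputs_marked_untested(self):
        spec = synthetic.SyntheticSpec()
        truth = synthetic.planted_truth(spec)
        report = synthetic.recovery_report(truth)
        assert report["rule_frequency"] == {"untested": True}
        assert report["lemma_freq"] == {"untested": True}
        assert report["mean_p_neg"] == {"untested": True}

    def test_planted_polarity_orders_the_groups(self, stub_lemmatizer, stub_scorer):
        spec = synthetic.SyntheticSpec(
            groups=(("opposition", 2, 150), ("control", 2, 150)), seed=77
        )
        truth, _r, _l, _s, summary = _recover(spec, stub_lemmatizer, stub_scorer)
        assert truth.group_order_p_neg == ("opposition", "control")
        assert summary.per_group["opposition"][0] > summary.per_group["control"][0]
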