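import pytest
from hypothesis import HealthCheck, settings

from socioscope import ingest, lexstats, privacy, sentiment, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> synthetic.SyntheticSpec:
    """A miniature study design: 2+2 chats of 120 messages."""
    return synthetic.SyntheticSpec(
        groups=(("opposition", 2, 120), ("control", 2, 120)),
        seed=123,
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec) -> ingest.Corpus:
    docs, _truth = synthetic.generate(small_spec)
    return ingest.build_corpus(
        [ingest.parse_export(d) for d in docs], synthetic.labels_for(small_spec)
    )


@pytest.fixture(scope="session")
def lexicons() -> privacy.ScrubLexicons:
    return privacy.ScrubLexicons.from_iterables(
        synthetic.NAME_LEXICON, synthetic.TOPONYM_LEXICON
    )


@pytest.fixture(scope="session")
def anon_corpus(small_corpus, lexicons):
    anon, _pmap = privacy.anonymize_corpus(small_corpus, lexicons, seed=11)
    return anon


@pytest.fixture(scope="session")
def stub_lemmatizer() -> lexstats.LookupLemmatizer:
    return lexstats.LookupLemmatizer(synthetic.LEMMA_MAP)


@pytest.fixture(scope="session")
def stub_scorer():
    return sentiment.lexicon_stub_scorer(synthetic.NEG_LEXICON, synthetic.POS_LEXICON)
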