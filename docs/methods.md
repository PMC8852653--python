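# Methods

## The analysis model

`socioscope` treats a collection of Telegram group chats as a two-group
observational design: a set of chats of interest (e.g. green-pass
opposition) and a set of control chats, with the **chat as the unit of
analysis**. Every quantitative output is first computed per chat and then
aggregated across the chats of a group; error bars are the standard error
of the mean across chats (sample sd with the n−1 denominator, divided by
√n). This avoids letting one very active chat dominate a group: a pooled
message-level average and the two-stage chat-then-group average genuinely
differ when chat sizes differ, and the test suite constructs such a case
to pin the two-stage rule.

### Eligibility screen

Control chats are screened for being alive and sizeable: at least 10
textual messages in the 7 days up to a reference date (inclusive bounds on
both ends) and at least 200 members. Export files do not record
membership, so the member count is an external input supplied in
configuration — this is documented loudly because it is the one eligibility
datum the tool cannot check itself. Timestamps are kept timezone-naive as
exported; eligibility uses date arithmetic on the naive values.

### Privacy transformation

Anonymization is placeholder substitution, applied mentions-first so that
`@marco` becomes `[username]` rather than `[name]`:

1. `@handle` → `[username]`, where a handle requires a non-word character
   (or start of string) before the `@`, so e-mail-like strings (`a@b`) are
   left alone;
2. lexicon first names → `[name]`, whole-word, case-insensitive;
3. lexicon toponyms → `[place]`, same matching rule.

Surnames are not scrubbed: in casual group chats they overwhelmingly refer
to public figures and sources, which carry analytical value. Detection is
lexicon-driven by default (deterministic, auditable); a named-entity
recognizer can be plugged behind the same contract. Pseudonyms are
sequential `user_NNNN` tokens assigned after a seeded shuffle of the
sorted sender-id set — deterministic for a fixed (id set, seed), but
unlinkable to insertion order. The transformation is idempotent
(placeholders contain nothing the scrubber targets), never mutates its
input corpus, and a sweep utility re-scans the output for residual
handles, names, or toponyms; the pipeline asserts the sweep comes back
empty. The CLI offers `--shred` to delete input files after a successful
anonymization; it is never on by default.

### Weighted dictionary autocoding

A concept ("code") is an ordered list of regular expressions. A message's
weight for a code is the number of **distinct** patterns with at least one
match — one firing rule gives weight 1, two give 2 — so repeated matches of
a single pattern do not inflate the weight. Occurrence counting is
available as an explicit option but is not the default reading.
Matching is case-insensitive (chat text is casually cased) with Unicode
word semantics so Italian diacritics count as word characters. Patterns
are standard Python `re` syntax, PCRE-compatible for the constructs used
in practice (`\s`, `\w`, `.`, `?`, alternation).

Per-chat **rule frequency** is message-level prevalence: 100 × (messages
with weight ≥ 1) / (textual messages in the chat). The denominator is all
textual messages because the weight system is message-level; weight-sum
normalization would conflate prevalence with within-message repetition.
Dictionary development is iterative by nature, so the engine also emits a
coverage report (per-pattern firing counts plus a sample of messages no
code matched) to guide refinement.

### Lemma analytics

Frequency analysis runs on lemmas, not surface forms. The retained token
stream drops punctuation, numerals, symbols, URLs, the three privacy
placeholders, and a configurable stoplist of Italian function words
(articles, prepositions, clitic pronouns, common conjunctions — the
default list lives in `lexstats.DEFAULT_STOPLIST`). Lemmas are case-folded
and NFC-normalized before counting. A table's `freq_pct` is
100·count/total over retained tokens and sums to 100 within 1e-9 for any
non-empty table; ties in top-N ranking break lexicographically so output
is reproducible.

The lemmatizer is a contract: the in-repo implementation is a
deterministic lookup table (exact on the synthetic vocabulary, usable as a
test double anywhere); `SpacyLemmatizer` adapts a pretrained Italian
pipeline for real corpora and is an optional extra precisely because model
weights are an external artifact.

### Sentiment

A scorer maps a message to the probability of negative polarity
(`p_neg ∈ [0,1]`, binary contract). The in-repo stub counts hits from
disjoint negative/positive word lists: `p_neg = n_neg/(n_neg+n_pos)`, 0.5
with no hits. The transformer adapter (optional extra) maps a binary
positive/negative softmax onto the same contract. Messages that are empty
after privacy transformation, or on which a scorer raises, are **skipped
and counted**, not default-scored at 0.5 — a 0.5 imputation would shrink
group differences by an amount that depends on the attachment rate, which
is a corpus property, not a sentiment signal.

### Group comparison

Group differences are tested with a two-sided t-test on the per-chat
vectors. Welch's unequal-variance statistic with Welch–Satterthwaite
degrees of freedom is the default — group sizes and variances differ in
any realistic design — with Student's pooled variant behind a flag. Stars:
`***` p<.001, `**` p<.01, `*` p<.05. No multiple-testing correction is
applied by default (each figure-level comparison is reported raw); a Holm
step-down helper is provided for users running many comparisons. Two
identical zero-variance samples return t=0, p=1 rather than NaN; two
constant samples with different means return ±∞ with p=0 (the test is
degenerate but the direction is certain).

### Qualitative export

Each subcorpus (typically: the messages on which one code fired) is
rendered as UTF-8 text with a light header grammar — `«pseudonym»
[code:weight,…]` — followed by the message text split on newlines. Line
positions count **text lines only** (headers excluded), 1-based and
contiguous, matching the "position = line in the subcorpus" convention
used when quoting; `locate` inverts the index so any quoted position can
be traced back to its message. Re-export is byte-identical: no timestamps
in the body, stable ordering.

## The synthetic generator

`synthetic.generate` emits one structurally valid Telegram-style export
per chat: sequential message ids and timestamps, a pool of sender ids with
display names, interleaved service entries (excluded from analytics), and
a fraction of messages rendered as entity arrays or `text_entities` to
exercise both export dialects. Message text is assembled from chunks:

- filler tokens drawn i.i.d. from a multinomial over a closed vocabulary
  of ~30 lemmas with known surface forms (zipf-like weights), so the
  lookup lemmatizer is exact and filler lemma counts are conditionally
  binomial given the filler total;
- exactly one sentiment token per message, negative with a per-group
  probability (default 0.6 opposition / 0.2 control), drawn from the
  stub scorer's own lexicons;
- per code, a dictionary-matching phrase inserted with a per-group
  probability (default green-pass 0.30 / 0.05, vaccine 0.20 / 0.08), so a
  chat's rule frequency is an exact Bernoulli rate;
- names, toponyms, and @-mentions inserted at low rates **from the scrub
  lexicons**, making the privacy-sweep assertion exact rather than
  statistical.

The default design mirrors a small two-group study: 4 opposition chats
(3 "university" + 1 "generic") versus 4 control chats, 500 messages each,
seed 7. A spec is validated before generation: every planted phrase must
match exactly its own code's dictionary, and no filler or sentiment token
may match any dictionary.

What the generator does **not** emulate: real Italian morphology and
syntax, reply graphs, temporal bursts, topic drift, out-of-lexicon named
entities, or sarcasm and other phenomena that defeat lexicon sentiment.
Passing tests therefore demonstrate that the machinery recovers known
structure from well-formed input — they say nothing about lemmatizer or
sentiment-model accuracy on real chat language, which must be assessed
with the pluggable production adapters.

### Recovery checking

`recovery_report` compares recovered counts with planted parameters using
exact central binomial acceptance regions (`binom.ppf` at 2.5% / 97.5%).
Lemma checks are restricted to filler lemmas so the conditional binomial
model is exact. Because each of the ~66 default quantities has ≥ 95%
marginal coverage, the end-to-end check asserts joint coverage as a
fraction — at least 93% of quantities inside their bands — rather than
all-of-them, which a 95% band does not promise.

## Test and simulation sizes

Type-I calibration runs 200 null corpora (4+4 chats × 80 messages, equal
planted parameters) and checks the α=.05 rejection count against the
exact binomial 95% band (4–16 of 200). The sentiment-separation check
runs the default design over 50 seeds. Unit and property tests use a
2+2 × 120 miniature of the default spec. These sizes give each check real
statistical teeth while keeping the default suite fast to run during
development.

## Known limitations

- Member counts for the eligibility screen must be supplied externally.
- Lexicon-driven scrubbing misses names absent from the lexicons; the NER
  adapter trades determinism for recall.
- Rule frequency is message-level prevalence by design; corpora where
  within-message repetition matters should use occurrence counting
  explicitly.
- The stoplist is a pragmatic function-word list, not a linguistic
  standard; published frequency values computed with a different stoplist will
  not be numerically reproduced.
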