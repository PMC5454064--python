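# Methods

## The suggestion model

The engine pairs free-text user posts with therapy content (steps and
actions) using three signals extracted from the post: sentiment,
a five-emotion profile, and keywords.

**Analyzer.** The analyzer is lexicon-based and deterministic.  Each
lexicon entry maps a lowercase token to a valence in [−1, 1] and a
(possibly empty) subset of {anger, disgust, fear, joy, sadness}.
Sentiment is the mean valence of matched tokens, clipped to [−1, 1];
a negator (`not`, `no`, `never`, or any token ending in `n't`) flips
the sign of the *immediately following* matched token only.  A post
matching no lexicon token scores exactly 0 (neutral).  Each emotion
score is the fraction of content tokens (non-stopword tokens)
carrying that emotion — a density, so it is bounded in [0, 1] and
monotone in emotional-token share.  Keywords are content tokens
ranked by frequency, ties to the earlier first occurrence, truncated
to k = 10.  Negator words double as stopwords: negation is resolved
on the raw token stream before stopword removal, so sentiment sees
them while emotion densities and keyword lists do not.

The analyzer is a replaceable backend: anything returning a valid
`PostAnalysis` (sentiment in [−1, 1], emotions in [0, 1]⁵,
duplicate-free keywords) can drive the engine.  Numerical agreement
with any particular commercial text-analysis service is a non-goal;
only the range/sign contract is binding.

**Valence gate.** Content is partitioned into items suitable for
positive posts, for negative posts, or for either.  A positive post
admits {positive, either}, a negative one {negative, either}, a
neutral one everything.  Admitting `either` items alongside the
matching pole is deliberate: reading the gate as pole-only would make
`either` items suggestible exclusively for neutral posts, defeating
their purpose.

**Score.** For an admitted item,

    score = α · sim + (1 − α) · cong,    α ∈ (0.5, 1], default 0.7

* `sim` — Dice coefficient 2|A∩B| / (|A|+|B|) between the post's and
  the item's keyword token sets, after normalisation (lowercasing,
  phrase splitting, stopword removal).  Two empty sets score 0.
* `cong` — 1 − (1/5) Σₑ |pₑ − rₑ| between the post's emotion vector
  and the item's emotion-relevance vector.

The α > 0.5 constraint encodes that keyword similarity is the
decisive factor while congruence is a balancing one: it separates
items with equal similarity and downgrades high-similarity items that
are emotionally inappropriate.  0.7 is the default split; it is a
convention, not a fitted value.  Steps and actions are scored as two
separate pools and one of each is selected, mirroring the platform
behaviour of suggesting one step and one action per post.

**Selection.** Argmax per pool.  Scores within 1e−9 of the maximum
form the tie set (floating-point equality being meaningless) and one
member is drawn uniformly with a `random.Random(seed)` instance
created per suggestion call — the step draw consumes the generator
before the action draw, so a (post, catalog, config) triple fully
determines the result.  A threshold τ (default 0, range [0, 1])
suppresses the suggestion for a pool whose best score falls below it.
A post with no extractable keywords has similarity 0 everywhere and
selection rides on congruence alone; this is documented behaviour,
not an error.

## Other channels

* **Related steps** are author-curated links stored on each step,
  returned in stored order — no scoring.
* **Newsfeed action suggestions** rank non-bookmarked actions by the
  count of shared chosen strengths plus shared sub-tags with taken
  steps; ties are broken by seeded random jitter.
* **Strengths page** is a pure filter: actions sharing ≥1 strength
  with the user's chosen five, sorted by title.
* **Search** is a case-insensitive substring match tiered
  title > keyword > sub-tag, ties alphabetical.  **Hidden Treasures**
  sorts steps by ascending visit count with never-visited steps
  first — the most aggressive reading of "least done", chosen because
  the list exists to counter informational cascades.  "Recently
  taken" uses all-time latest visit (no recency window is specified;
  the window is configurable by pre-filtering the event list).
* **Analytics** tallies the moderator-suggestion ledger
  (completed / client-dismissed / moderator-dismissed / pending) and
  access-path shares.  The three share denominators quoted for a live
  deployment ("visits to steps/actions", "step visits", "action/step
  visits") are mutually inconsistent; this package unifies them as
  all tracked step+action visits, with a per-kind filter available.
* **Chatbot** is a two-slot (mood, topic) finite-state machine with
  at most two reprompts per slot, after which the slot is skipped
  empty; the dialog therefore terminates within a fixed turn bound
  for any input.  The concatenated slots are processed *exactly* as a
  newsfeed post — the bot adds no second scoring path — and the
  result forms the moderator-facing pre-chat profile.  Reply wording
  lives in `data/chat_replies.json`.

## Synthetic data

`generate_catalog` draws valences, emotion vectors, keywords, tags,
strengths and (always-resolving) related links from seeded uniform
choices; every generated catalog passes full validation.
`generate_posts` samples content tokens from lexicon strata: when an
emotion is targeted, ~65 % of content tokens carry it and the rest is
emotion-free filler, with stopwords interleaved (~30 % of the final
stream) for surface realism; 30–50 content tokens per post by
default.  The 65 % share was chosen as a realistic "clearly but not
uniformly emotional" density; with ≥30 content tokens it makes the
targeted emotion the analyzer argmax in essentially all replicates.

The canonical accounting fixtures are deterministic reconstructions:
a 701-record ledger with outcome counts 211/21/304/165, and two
100-event logs whose access-path splits are 48/14/11/27 (the four
popularity links) and 39/5/9/47 (moderator suggestions, post-step
related list, newsfeed suggestions, everything else).  Scaling the
logs to exactly 100 events makes the integer percentages exact rather
than approximate.  The taxonomy is the canonical 3×3 set of named
sub-tags; of the 24 character strengths only four names are
platform-attested (Courage, Discretion, Creativity, Curiosity) — the
other 20 are synthetic stand-ins.

What passing tests on this synthetic data shows — and does not: the
generators exercise the engine's *contracts* (ranges, partitioning,
argmax, determinism, tie uniformity) over a wide space of catalogs
and token mixes, but synthetic posts are bags of lexicon words, not
real user language; nothing here validates clinical relevance or
live-deployment engagement, and the ledger/share figures are
reconstructions of reported accounting, not re-measurements.

## Numerical and design choices

* Tie tolerance 1e−9 on combined scores (absolute; scores live in
  [0, 1]).
* Validation is collect-all: every violation in a catalog, event log
  or ledger file is reported at once.
* Steps may carry strengths (only actions require them); empty sets
  are allowed — forward compatibility at no cost.
* Popularity-list ties break by id; truncation to k (default 10)
  never reorders.
* Test and acceptance problem sizes — 200 random instances of ≤ 50
  items, 200 replicates per emotion, 1000 tie-break seeds, 10 000
  fuzz streams — keep the whole suite under a few seconds while the
  statistical assertions (≥95 % recovery, 50 ± 5 % tie split) remain
  comfortably powered.

## Known limitations

* The bundled lexicon is small (~85 entries) and English-only; it is
  meant as a reproducible default, not a linguistic resource.  Larger
  lexicons load through the same TSV format.
* Keyword extraction is unigram frequency — no phrase chunking or
  semantics; the similarity function is pluggable where more is
  needed.
* Negation handling is a one-token window; "not very happy" escapes
  the flip.
* The chatbot is a scripted elicitor, not a conversational agent; no
  risk/crisis detection of any kind is attempted.
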