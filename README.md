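# therapyrec

A deterministic, fully local implementation of the automated
therapy-content suggestion machinery used by moderated online social
therapy platforms — web applications where young people recovering
from mental ill-health mix peer social networking with interactive
therapy modules ("steps") and real-world behavioural tasks
("actions"), under the eye of clinician moderators.

It is written for researchers and engineers who want to study,
reproduce or extend that recommendation machinery without a live
platform or a remote text-analysis API: everything here runs offline,
is seeded, and is testable.

## What it does

When a user posts to the newsfeed, the engine:

1. **analyzes the post** with a lexicon-based analyzer: a sentiment
   score *s* ∈ [−1, 1] (0 neutral, >0 positive, <0 negative), a score
   in [0, 1] for each of the five emotions anger, disgust, fear, joy
   and sadness (the density of tokens carrying the emotion among
   content tokens), and frequency-ranked keywords;
2. **partitions candidates by valence**: each step/action is marked
   suitable for *positive* posts, *negative* posts, or *either*;
   positive posts only see {positive, either} items, negative posts
   {negative, either}, neutral posts everything;
3. **scores each admitted candidate** as

   `score = α · sim + (1 − α) · cong`,  α = 0.7 by default,

   where `sim` is the Dice coefficient `2|A∩B| / (|A|+|B|)` between
   the post's and the item's normalised keyword token sets and
   `cong = 1 − (1/5) Σₑ |pₑ − rₑ|` is the congruence between the
   post's emotion vector *p* and the item's emotion-relevance vector
   *r*.  Similarity dominates; congruence adjudicates between items
   with equal similarity and downgrades emotionally inappropriate ones;
4. **selects** the highest-scoring step and the highest-scoring
   action, breaking exact ties uniformly at random under a seed, with
   a full per-candidate audit trail.

Around this core the package implements the platform's other content
channels: author-curated related steps, strengths/history-driven
newsfeed action suggestions, the "Powered by your Strengths" page
(choose 5 of 24 character strengths), basic text search, the
alphabetical step browse, the four popularity rankings (including
*Hidden Treasures*, which surfaces the least-taken steps to counter
informational cascades), engagement analytics over usage-event logs
and the moderator-suggestion ledger, and a minimal rule-based
conversational search bot that produces a pre-chat profile for a
human moderator.

## Worked example

```bash
therapyrec suggest \
  --post "Feeling stressed about my new job" \
  --catalog example_catalog.json --seed 1 --audit
```

(`example_catalog.json` here is the small catalog bundled at
`therapyrec/data/example_catalog.json`; `therapyrec fixtures build
--out DIR` writes it and the other fixture files for you.)  Output,
abridged:

```json
{
  "step": "step-work-study",
  "step_title": "Thriving at Work and Study",
  "action": "action-breathing-break",
  "action_title": "Take a Breathing Break at Work",
  "sentiment_class": "negative",
  "sentiment": -0.6,
  "emotions": {"anger": 0.0, "disgust": 0.0, "fear": 0.5, "joy": 0.0, "sadness": 0.0},
  "keywords": ["stressed", "job"],
  "audit": [
    {"id": "step-work-study", "admitted": true,
     "similarity": 0.5, "congruence": 0.84, "combined": 0.602},
    {"id": "step-mindfulness", "admitted": true,
     "similarity": 0.0, "congruence": 0.8, "combined": 0.24},
    {"id": "step-relationships", "admitted": false, "...": "..."}
  ]
}
```

Reading it: "stressed" carries fear with valence −0.6, so the post is
negative with fear density 0.5; the positively-valenced relationships
step is therefore excluded (`admitted: false`).  Among admitted
steps, the work/study step shares two of four keyword tokens with the
post (Dice 0.5) and has the closest emotion profile (congruence
0.84), so its combined score 0.7·0.5 + 0.3·0.84 = 0.602 wins.

The same library surface is available in Python:

```python
import therapyrec as tr
cat = tr.example_catalog()
res = tr.suggest("Feeling stressed about my new job", cat,
                 cfg=tr.ScoringConfig(seed=1))
print(res.step)   # step-work-study
```

Other subcommands: `analyze`, `search`, `rank`, `stats outcomes`,
`stats shares`, `chat`, `fixtures build`, `catalog validate`.

## Layout

* `src/therapyrec/catalog.py` — content model, validation, JSON I/O
* `src/therapyrec/text_analysis.py` — lexicon analyzer
* `src/therapyrec/engine.py` — suggestion scoring and selection
* `src/therapyrec/discovery.py` — search, browse, popularity lists
* `src/therapyrec/analytics.py` — event-log / ledger accounting
* `src/therapyrec/chatbot.py` — slot-filling conversational search
* `src/therapyrec/fixtures.py` — seeded generators, canonical fixtures
* `src/therapyrec/cli.py` — the `therapyrec` command

See `docs/methods.md` for the model, its assumptions and the design
choices behind it.
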