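"""Synthetic inputs: seeded post/catalog generators and the canonical
reference fixtures.

The generators make every module testable without any external data.
``generate_posts`` draws content tokens from lexicon strata so that a
post can be *targeted* at an emotion or sentiment sign — the basis of
parameter-recovery testing of the analyzer.  ``generate_catalog``
produces validation-clean catalogs of any size.

``build_canonical_fixtures`` reconstructs, deterministically, the
reference accounting inputs: a 701-record moderator-suggestion ledger
(211 completed / 21 client-dismissed / 304 moderator-dismissed /
165 pending), a 100-event log for the four popularity links split
48/14/11/27, a 100-event tracked-visit log split 39/5/9/47, the
canonical 3x3 tag taxonomy, and the 24-strength list.  Only four of
the 24 strength names are platform-attested (Courage, Discretion,
Creativity, Curiosity); the other 20 are synthetic stand-ins.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

from .analytics import (SuggestionRecord, UsageEvent, write_events,
                        write_ledger)
from .catalog import (EMOTIONS, Catalog, TagTaxonomy, TherapyItem,
                      save_catalog, validate_catalog)
from .errors import UsageError, ValidationError
from .text_analysis import Lexicon, default_lexicon

CANONICAL_TAXONOMY = TagTaxonomy(
    parents=("Coping", "Connecting", "Enhancing"),
    children={
        "Coping": ("Solving Problems", "Kicking the Habit",
                   "Beating Sadness and Worries"),
        "Connecting": ("Overcoming Conflict", "Boosting Relationships",
                       "Stories Like Yours"),
        "Enhancing": ("Making Happiness", "Wellbeing with Mindfulness",
                      "Work and Study"),
    },
)

#: first four are platform-attested; the remaining 20 are synthetic
CANONICAL_STRENGTHS = (
    "Courage", "Discretion", "Creativity", "Curiosity",
    "Kindness", "Gratitude", "Hope", "Humor", "Honesty", "Perseverance",
    "Teamwork", "Fairness", "Leadership", "Forgiveness", "Humility",
    "Zest", "Love of Learning", "Perspective", "Social Intelligence",
    "Self-Regulation", "Appreciation of Beauty", "Spirituality",
    "Enthusiasm", "Patience",
)

#: ledger outcome counts of the reference deployment
LEDGER_COUNTS = {"completed": 211, "client_dismissed": 21,
                 "moderator_dismissed": 304, "pending": 165}

#: four-popularity-link visit split (percent of 100 events)
FOUR_LINK_COUNTS = {"steps_recent": 48, "steps_talking": 14,
                    "steps_often": 11, "hidden_treasures": 27}

#: tracked-visit split (percent of 100 events)
TRACKED_COUNTS = {"moderator_suggestion": 39, "related_after_step": 5,
                  "newsfeed_suggestion": 9, "other": 47}

_TITLE_WORDS = ("Calm", "Focus", "Courage", "Kindness", "Balance", "Energy",
                "Gratitude", "Strength", "Clarity", "Connection", "Rest",
                "Growth", "Purpose", "Resilience", "Patience", "Hope")

_KEYWORD_POOL = ("work", "job", "study", "school", "exam", "sleep", "friend",
                 "family", "stress", "mindfulness", "breathing", "exercise",
                 "walk", "music", "talk", "conflict", "habit", "worry",
                 "happiness", "relationship", "problem", "goal", "routine",
                 "support", "confidence", "relax", "focus", "energy")


@dataclass(frozen=True)
class GenerationSpec:
    """Knobs of the seeded generators."""

    seed: int = 0
    n_posts: int = 0
    n_steps: int = 0
    n_actions: int = 0
    target_emotion: str | None = None
    target_sentiment_sign: str = "0"  # "+", "0", "-"
    min_tokens: int = 30
    max_tokens: int = 50

    def __post_init__(self):
        if min(self.n_posts, self.n_steps, self.n_actions) < 0:
            raise ValueError("sizes must be >= 0")
        if not 0 < self.min_tokens <= self.max_tokens:
            raise ValueError("token bounds must be positive and ordered")
        if self.target_emotion is not None and self.target_emotion not in EMOTIONS:
            raise ValueError(f"unknown target emotion {self.target_emotion!r}")
        if self.target_sentiment_sign not in ("+", "0", "-"):
            raise ValueError("target_sentiment_sign must be '+', '0' or '-'")


def _strata(lexicon: Lexicon) -> dict[str, list[str]]:
    strata: dict[str, list[str]] = {e: [] for e in EMOTIONS}
    strata.update({"+": [], "-": [], "0": []})
    for tok, (val, emos) in sorted(lexicon.entries.items()):
        for e in emos:
            strata[e].append(tok)
        if val > 0:
            strata["+"].append(tok)
        elif val < 0:
            strata["-"].append(tok)
    # emotion-free, valence-free filler comes from outside the lexicon
    strata["0"] = [t for t in _KEYWORD_POOL if t not in lexicon.entries]
    return strata


def generate_posts(spec: GenerationSpec, lexicon: Lexicon | None = None) -> list[str]:
    """Seeded synthetic posts drawn from lexicon strata.

    When an emotion is targeted, roughly 65% of content tokens carry it
    (with valences of the targeted sign where one is also requested);
    the rest is neutral filler.  Stopwords are interleaved for surface
    realism.  Identical specs yield identical posts.
    """
    lexicon = lexicon or default_lexicon()
    strata = _strata(lexicon)
    for e in EMOTIONS:
        if not strata[e]:
            raise UsageError(f"lexicon has no token carrying emotion {e!r}")
    for sign in ("+", "-"):
        if not strata[sign]:
            raise UsageError(f"lexicon has no token with {sign!r} valence")

    rng = random.Random(spec.seed)
    stop_pool = sorted(lexicon.stopwords) or ["the"]

    if spec.target_emotion is not None:
        main_pool = strata[spec.target_emotion]
        if spec.target_sentiment_sign != "0":
            signed = [t for t in main_pool
                      if t in set(strata[spec.target_sentiment_sign])]
            main_pool = signed or main_pool
    elif spec.target_sentiment_sign != "0":
        main_pool = strata[spec.target_sentiment_sign]
    else:
        main_pool = strata["0"]
    filler_pool = strata["0"] or main_pool

    posts: list[str] = []
    for _ in range(spec.n_posts):
        n_content = rng.randint(spec.min_tokens, spec.max_tokens)
        words: list[str] = []
        for _ in range(n_content):
            pool = main_pool if rng.random() < 0.65 else filler_pool
            words.append(rng.choice(pool))
        # interleave stopwords (~30% of the final stream)
        out: list[str] = []
        for w in words:
            if rng.random() < 0.3:
                out.append(rng.choice(stop_pool))
            out.append(w)
        posts.append(" ".join(out))
    return posts


def generate_catalog(spec: GenerationSpec) -> Catalog:
    """Seeded, validation-clean catalog of ``n_steps`` + ``n_actions``
    items with random valences, emotion vectors, keywords, sub-tags,
    strengths and (resolving) related-step links."""
    rng = random.Random(spec.seed)
    subtags = CANONICAL_TAXONOMY.subtags()
    step_ids = [f"step{i:03d}" for i in range(spec.n_steps)]
    items: list[TherapyItem] = []
    for kind, ids in (("step", step_ids),
                      ("action", [f"action{i:03d}" for i in range(spec.n_actions)])):
        for iid in ids:
            title = " ".join(rng.sample(_TITLE_WORDS, 2)) + f" {iid[-3:]}"
            relevance = {e: round(rng.random(), 3) for e in EMOTIONS}
            keywords = frozenset(rng.sample(_KEYWORD_POOL, rng.randint(2, 5)))
            tags = frozenset(rng.sample(subtags, rng.randint(1, 2)))
            strengths = (frozenset(rng.sample(CANONICAL_STRENGTHS, rng.randint(1, 3)))
                         if kind == "action" else frozenset())
            related: tuple[str, ...] = ()
            if kind == "step" and len(step_ids) > 1:
                others = [s for s in step_ids if s != iid]
                n_rel = rng.randint(0, min(3, len(others)))
                related = tuple(rng.sample(others, n_rel))
            items.append(TherapyItem(
                id=iid, kind=kind, title=title,
                valence=rng.choice(("positive", "negative", "either")),
                emotion_relevance=relevance, keywords=keywords,
                subtags=tags, strengths=strengths, related_ids=related,
            ))
    catalog = Catalog(items=tuple(items), taxonomy=CANONICAL_TAXONOMY,
                      strengths=CANONICAL_STRENGTHS)
    problems = validate_catalog(catalog)
    if problems:  # constructive guarantee; reaching this is a bug
        raise ValidationError(problems)
    return catalog


def example_catalog() -> Catalog:
    """The small worked-example catalog bundled with the package."""
    from importlib import resources

    from .catalog import catalog_from_dict
    text = (resources.files("therapyrec.data") / "example_catalog.json").read_text("utf-8")
    import json
    return catalog_from_dict(json.loads(text))


def _ts(i: int) -> datetime:
    return datetime(2017, 1, 1) + timedelta(minutes=i)


def build_canonical_fixtures() -> dict:
    """Deterministic (seed-free) reference fixtures: ledger, event logs,
    taxonomy and strengths.  Byte-stable across runs."""
    ledger = []
    i = 0
    for status in ("completed", "client_dismissed", "moderator_dismissed", "pending"):
        for _ in range(LEDGER_COUNTS[status]):
            i += 1
            ledger.append(SuggestionRecord(
                record_id=f"sg{i:04d}", moderator_id=f"mod{(i % 8) + 1}",
                user_id=f"user{(i % 60) + 1:03d}", item_id=f"step{(i % 40):03d}",
                status=status,
            ))

    four_link = []
    i = 0
    for path, n in FOUR_LINK_COUNTS.items():
        for _ in range(n):
            i += 1
            four_link.append(UsageEvent(
                user_id=f"user{(i % 50) + 1:03d}", item_id=f"step{(i % 30):03d}",
                item_kind="step", access_path=path, timestamp=_ts(i),
            ))

    tracked = []
    i = 0
    for path, n in TRACKED_COUNTS.items():
        for _ in range(n):
            i += 1
            tracked.append(UsageEvent(
                user_id=f"user{(i % 50) + 1:03d}",
                item_id=(f"action{(i % 20):03d}" if i % 3 == 0 else f"step{(i % 30):03d}"),
                item_kind=("action" if i % 3 == 0 else "step"),
                access_path=path, timestamp=_ts(i),
            ))

    return {
        "ledger": ledger,
        "four_link_events": four_link,
        "tracked_events": tracked,
        "taxonomy": CANONICAL_TAXONOMY,
        "strengths": CANONICAL_STRENGTHS,
    }


def write_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write all fixture files (canonical logs plus one seeded demo
    catalog) into ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = build_canonical_fixtures()
    paths = []

    p = out / "suggestion_ledger.csv"
    write_ledger(fx["ledger"], p)
    paths.append(p)
    p = out / "four_link_events.csv"
    write_events(fx["four_link_events"], p)
    paths.append(p)
    p = out / "tracked_events.csv"
    write_events(fx["tracked_events"], p)
    paths.append(p)

    demo = generate_catalog(GenerationSpec(seed=seed, n_steps=12, n_actions=8))
    p = out / "demo_catalog.json"
    save_catalog(demo, p)
    paths.append(p)
    return paths
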