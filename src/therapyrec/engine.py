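"""Automated therapy-content suggestion.

The core pipeline mirrors how a post on the platform's newsfeed turns
into one suggested step and one suggested action:

1. analyze the post (sentiment, five emotions, keywords);
2. partition candidates by valence — positive posts only see items
   marked ``positive`` or ``either``, negative posts ``negative`` or
   ``either``, neutral posts see everything;
3. score every admitted candidate as a convex combination of keyword
   similarity (Dice coefficient on normalised token sets) and emotion
   congruence (one minus mean absolute difference of the five-emotion
   vectors), with similarity carrying the dominant weight;
4. select the top-scoring step and top-scoring action, breaking exact
   ties uniformly at random under a caller-supplied seed.

Two further automated channels are provided: author-curated related
steps shown after completing a step, and newsfeed action suggestions
driven by the user's chosen strengths and step history.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .catalog import EMOTIONS, Catalog, TherapyItem
from .errors import DomainError
from .text_analysis import Lexicon, PostAnalysis, analyze_post, default_lexicon

#: weight on keyword similarity; must dominate (alpha > 0.5) so that
#: similarity is the decisive factor and congruence the adjudicator
DEFAULT_ALPHA = 0.7

#: exact-tie tolerance on combined scores
TIE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class ScoringConfig:
    """Tunables of the combined score and tie-breaking.

    alpha
        weight on semantic similarity, in (0.5, 1].  The complement
        ``1 - alpha`` weights emotion congruence.
    tau
        minimum combined score in [0, 1]; if no admitted candidate
        reaches it, no suggestion is emitted for that kind.  The
        default 0 always suggests when candidates exist.
    seed
        integer seeding the uniform random tie-break.
    """

    alpha: float = DEFAULT_ALPHA
    tau: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.5 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0.5, 1], got {self.alpha}")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")


@dataclass(frozen=True)
class CandidateAudit:
    """Per-candidate scoring record kept for moderator-style review."""

    id: str
    kind: str
    admitted: bool
    similarity: float
    congruence: float
    combined: float


@dataclass(frozen=True)
class SuggestionResult:
    """Selected step and action (either may be None) plus the full
    per-candidate audit trail."""

    step: str | None
    action: str | None
    audit: tuple[CandidateAudit, ...]
    sentiment_class: str
    tie_broken: bool
    analysis: PostAnalysis


@dataclass(frozen=True)
class UserProfile:
    """What the engine knows about one user."""

    user_id: str
    chosen_strengths: frozenset[str] = frozenset()
    steps_taken: frozenset[str] = frozenset()
    bookmarked_actions: frozenset[str] = frozenset()


def partition_candidates(items: list[TherapyItem] | tuple[TherapyItem, ...],
                         sentiment: float) -> list[TherapyItem]:
    """Valence gate: positive posts admit {positive, either}, negative
    posts {negative, either}, neutral posts everything.  Order kept."""
    if sentiment > 0:
        allowed = {"positive", "either"}
    elif sentiment < 0:
        allowed = {"negative", "either"}
    else:
        return list(items)
    return [it for it in items if it.valence in allowed]


def normalize_keywords(keywords, lexicon: Lexicon) -> frozenset[str]:
    """Lowercase, split phrases into tokens, drop stopwords."""
    out: set[str] = set()
    for kw in keywords:
        for tok in str(kw).lower().split():
            tok = tok.strip("'\"?!.,;:()")
            if tok and tok not in lexicon.stopwords:
                out.add(tok)
    return frozenset(out)


def semantic_similarity(a: frozenset[str] | set[str],
                        b: frozenset[str] | set[str]) -> float:
    """Dice coefficient 2|a∩b| / (|a|+|b|) on token sets; 0 if both empty."""
    if not a and not b:
        return 0.0
    return 2.0 * len(set(a) & set(b)) / (len(a) + len(b))


def emotion_congruence(p: dict[str, float], r: dict[str, float]) -> float:
    """1 - mean absolute difference over the five emotions; in [0, 1]."""
    return 1.0 - sum(abs(p[e] - r[e]) for e in EMOTIONS) / len(EMOTIONS)


def score_item(analysis: PostAnalysis, item: TherapyItem, cfg: ScoringConfig,
               lexicon: Lexicon) -> tuple[float, float, float]:
    """(similarity, congruence, combined) for one candidate."""
    sim = semantic_similarity(
        normalize_keywords(analysis.keywords, lexicon),
        normalize_keywords(item.keywords, lexicon),
    )
    cong = emotion_congruence(analysis.emotions, item.emotion_relevance)
    return sim, cong, cfg.alpha * sim + (1.0 - cfg.alpha) * cong


def _select(pool: list[TherapyItem], admitted_ids: set[str],
            scores: dict[str, float], cfg: ScoringConfig,
            rng: random.Random) -> tuple[str | None, bool]:
    """Argmax over admitted candidates; exact ties (within TIE_TOLERANCE)
    broken uniformly at random; below-tau maxima yield no selection."""
    candidates = [it.id for it in pool if it.id in admitted_ids]
    if not candidates:
        return None, False
    best = max(scores[c] for c in candidates)
    if best < cfg.tau:
        return None, False
    tie_set = sorted(c for c in candidates if abs(scores[c] - best) <= TIE_TOLERANCE)
    if len(tie_set) == 1:
        return tie_set[0], False
    return rng.choice(tie_set), True


def suggest_from_analysis(analysis: PostAnalysis, catalog: Catalog,
                          cfg: ScoringConfig | None = None,
                          lexicon: Lexicon | None = None) -> SuggestionResult:
    """Run steps 2-4 of the pipeline on an already-analyzed post.

    Steps and actions are partitioned and scored as separate pools; one
    of each is selected.  Deterministic in (analysis, catalog, cfg).
    """
    cfg = cfg or ScoringConfig()
    lexicon = lexicon or default_lexicon()
    rng = random.Random(cfg.seed)

    audit: list[CandidateAudit] = []
    scores: dict[str, float] = {}
    admitted_ids: set[str] = set()
    for kind in ("step", "action"):
        pool = [it for it in catalog.items if it.kind == kind]
        admitted = partition_candidates(pool, analysis.sentiment)
        admitted_ids.update(it.id for it in admitted)
        for it in pool:
            sim, cong, combined = score_item(analysis, it, cfg, lexicon)
            scores[it.id] = combined
            audit.append(CandidateAudit(
                id=it.id, kind=kind, admitted=it.id in admitted_ids,
                similarity=sim, congruence=cong, combined=combined,
            ))

    step_id, step_tie = _select(
        [it for it in catalog.items if it.kind == "step"], admitted_ids, scores, cfg, rng)
    action_id, action_tie = _select(
        [it for it in catalog.items if it.kind == "action"], admitted_ids, scores, cfg, rng)

    return SuggestionResult(
        step=step_id,
        action=action_id,
        audit=tuple(audit),
        sentiment_class=analysis.sentiment_class,
        tie_broken=step_tie or action_tie,
        analysis=analysis,
    )


def suggest(post_text: str, catalog: Catalog,
            profile: UserProfile | None = None,
            cfg: ScoringConfig | None = None,
            lexicon: Lexicon | None = None) -> SuggestionResult:
    """Analyze a post and suggest one step and one action.

    ``profile`` is accepted for interface symmetry with the other
    channels; post-triggered suggestions depend only on the post text.
    An empty catalog yields a result with both selections None.
    """
    lexicon = lexicon or default_lexicon()
    analysis = analyze_post(post_text, lexicon)
    return suggest_from_analysis(analysis, catalog, cfg, lexicon)


def related_steps(step_id: str, catalog: Catalog) -> list[TherapyItem]:
    """The author-curated "You might also be interested in" list: the
    step's related ids resolved to items, in stored order."""
    item = catalog[step_id]  # raises DomainError if unknown
    if item.kind != "step":
        raise DomainError(f"{step_id!r} is not a step")
    return [catalog[rid] for rid in item.related_ids]


def feed_action_suggestions(profile: UserProfile, catalog: Catalog,
                            n: int = 3, seed: int = 0) -> list[TherapyItem]:
    """Newsfeed action placements driven by chosen strengths and step
    history.

    Candidates share at least one strength with the profile's chosen
    strengths or at least one sub-tag with a step the user has taken;
    ranked by (shared-strength count + shared-subtag count) descending
    with seeded-random tie-breaking; bookmarked actions excluded; at
    most ``n`` returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    taken_subtags: set[str] = set()
    for sid in profile.steps_taken:
        if sid in catalog:
            taken_subtags.update(catalog[sid].subtags)

    scored: list[tuple[int, str]] = []
    for it in catalog.actions:
        if it.id in profile.bookmarked_actions:
            continue
        n_str = len(it.strengths & profile.chosen_strengths)
        n_tag = len(it.subtags & taken_subtags)
        if n_str + n_tag > 0:
            scored.append((n_str + n_tag, it.id))

    rng = random.Random(seed)
    # stable id order first so the seeded jitter is reproducible
    scored.sort(key=lambda t: t[1])
    jitter = {iid: rng.random() for _, iid in scored}
    scored.sort(key=lambda t: (-t[0], jitter[t[1]]))
    return [catalog[iid] for _, iid in scored[:n]]


def strengths_page_actions(profile: UserProfile, catalog: Catalog) -> list[TherapyItem]:
    """The "Powered by your Strengths" page: exactly the actions sharing
    at least one strength with the user's chosen strengths, by title."""
    hits = [it for it in catalog.actions
            if it.strengths & profile.chosen_strengths]
    return sorted(hits, key=lambda it: (it.title, it.id))
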