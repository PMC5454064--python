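"""Independent brute-force oracle for the suggestion pipeline.

Re-derives the valence partition, the Dice/congruence scores and the
argmax selection with naive loops, sharing no code with the engine
beyond the post analysis it consumes.  Also builds randomized
(post, catalog, config) instances for equivalence testing.
"""

from __future__ import annotations

import random

import therapyrec as tr
from therapyrec.catalog import EMOTIONS


def _norm_tokens(keywords, lexicon):
    toks = set()
    for kw in keywords:
        for t in str(kw).lower().split():
            t = t.strip("'\"?!.,;:()")
            if t and t not in lexicon.stopwords:
                toks.add(t)
    return toks


def _dice(a, b):
    if len(a) == 0 and len(b) == 0:
        return 0.0
    inter = 0
    for t in a:
        if t in b:
            inter += 1
    return 2.0 * inter / (len(a) + len(b))


def _congruence(p, r):
    total = 0.0
    for e in EMOTIONS:
        d = p[e] - r[e]
        total += d if d >= 0 else -d
    return 1.0 - total / 5.0


def _admitted(item, sentiment):
    if sentiment > 0:
        return item.valence in ("positive", "either")
    if sentiment < 0:
        return item.valence in ("negative", "either")
    return True


def oracle_suggest(post_text, catalog, cfg, lexicon):
    """Brute-force (step_id, action_id) selection for a post."""
    analysis = tr.analyze_post(post_text, lexicon)
    post_kw = _norm_tokens(analysis.keywords, lexicon)
    rng = random.Random(cfg.seed)
    picks = {}
    for kind in ("step", "action"):
        best_ids, best_score = [], None
        for item in catalog.items:
            if item.kind != kind or not _admitted(item, analysis.sentiment):
                continue
            sim = _dice(post_kw, _norm_tokens(item.keywords, lexicon))
            cong = _congruence(analysis.emotions, item.emotion_relevance)
            score = cfg.alpha * sim + (1 - cfg.alpha) * cong
            if best_score is None or score > best_score + 1e-9:
                best_ids, best_score = [item.id], score
            elif abs(score - best_score) <= 1e-9:
                best_ids.append(item.id)
        if best_score is None or best_score < cfg.tau:
            picks[kind] = None
        elif len(best_ids) == 1:
            picks[kind] = best_ids[0]
        else:
            picks[kind] = rng.choice(sorted(best_ids))
    return picks["step"], picks["action"]


def make_instance(seed, lexicon, max_items=50):
    """One randomized (post_text, catalog, cfg) equivalence-test case.

    Catalogs stay at or below ``max_items`` items; with some
    probability an item is cloned under a new id so that exact score
    ties genuinely occur and exercise the seeded tie-break.
    """
    rng = random.Random(seed)
    n_steps = rng.randint(1, max_items // 2)
    n_actions = rng.randint(1, max_items - n_steps - 2)
    catalog = tr.generate_catalog(
        tr.GenerationSpec(seed=rng.randrange(2**31), n_steps=n_steps,
                          n_actions=n_actions))

    if rng.random() < 0.4:  # force an exact-score tie via a clone
        src = rng.choice(catalog.items)
        clone = tr.TherapyItem(
            id=src.id + "-twin", kind=src.kind, title=src.title + " Twin",
            valence=src.valence, emotion_relevance=dict(src.emotion_relevance),
            keywords=src.keywords, subtags=src.subtags,
            strengths=src.strengths, related_ids=())
        catalog = tr.Catalog(items=catalog.items + (clone,),
                             taxonomy=catalog.taxonomy,
                             strengths=catalog.strengths)

    style = rng.random()
    if style < 0.4:
        emotion = rng.choice(EMOTIONS)
        sign = rng.choice(("+", "-", "0"))
        post = tr.generate_posts(
            tr.GenerationSpec(seed=rng.randrange(2**31), n_posts=1,
                              target_emotion=emotion,
                              target_sentiment_sign=sign,
                              min_tokens=5, max_tokens=25),
            lexicon)[0]
    elif style < 0.8:
        pool = sorted({kw for it in catalog.items for kw in it.keywords})
        pool += sorted(lexicon.entries)[:20]
        post = " ".join(rng.choice(pool) for _ in range(rng.randint(3, 20)))
    else:
        post = ""  # no keywords: selection rides on congruence alone

    cfg = tr.ScoringConfig(alpha=rng.uniform(0.55, 1.0),
                           tau=rng.choice((0.0, 0.0, 0.3)),
                           seed=rng.randrange(2**31))
    return post, catalog, cfg
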