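import random
from collections import Counter

import pytest

import therapyrec as tr
from oracle import make_instance, oracle_suggest
from therapyrec.catalog import EMOTIONS, TherapyItem


def _item(iid, kind="step", valence="either", keywords=("x",),
          relevance=None, **kw):
    return TherapyItem(
        id=iid, kind=kind, title=iid.title(), valence=valence,
        emotion_relevance=relevance or {e: 0.0 for e in EMOTIONS},
        keywords=frozenset(keywords),
        subtags=frozenset({"Work and Study"}), **kw)


@pytest.mark.parametrize("sentiment, expected_ids", [
    (0.6, ["a", "c"]),
    (-0.2, ["b", "c"]),
    (0.0, ["a", "b", "c"]),
])
def test_valence_partition(sentiment, expected_ids):
    """Positive posts admit positive+either, negative posts
    negative+either, neutral posts everything; order preserved."""
    items = [_item("a", valence="positive"), _item("b", valence="negative"),
             _item("c", valence="either")]
    got = tr.partition_candidates(items, sentiment)
    assert [it.id for it in got] == expected_ids


@pytest.mark.parametrize("a, b, expected", [
    ({"work", "stress"}, {"work", "stress"}, 1.0),
    ({"work"}, {"calm"}, 0.0),
    ({"stress", "work"}, {"work", "mindfulness"}, 0.5),
    (set(), set(), 0.0),
])
def test_dice_similarity(a, b, expected):
    assert tr.semantic_similarity(a, b) == pytest.approx(expected)


@pytest.mark.parametrize("p, r, expected", [
    ({e: 0.3 for e in EMOTIONS}, {e: 0.3 for e in EMOTIONS}, 1.0),
    ({e: 0.0 for e in EMOTIONS}, {e: 1.0 for e in EMOTIONS}, 0.0),
    (dict(zip(EMOTIONS, [0.5, 0, 0, 0, 0])), {e: 0.0 for e in EMOTIONS}, 0.9),
])
def test_emotion_congruence(p, r, expected):
    assert tr.emotion_congruence(p, r) == pytest.approx(expected)


def test_combined_score_is_convex_combination(lexicon):
    """combined = alpha * similarity + (1 - alpha) * congruence."""
    cfg = tr.ScoringConfig(alpha=0.7)
    analysis = tr.PostAnalysis(
        sentiment=0.0, emotions=dict(zip(EMOTIONS, [0.5, 0, 0, 0, 0])),
        keywords=("stress", "work"))
    item = _item("a", keywords=("work", "mindfulness"))
    sim, cong, combined = tr.score_item(analysis, item, cfg, lexicon)
    assert sim == pytest.approx(0.5)
    assert cong == pytest.approx(0.9)
    assert combined == pytest.approx(0.7 * 0.5 + 0.3 * 0.9)


def test_scoring_config_validation():
    with pytest.raises(ValueError):
        tr.ScoringConfig(alpha=0.5)
    with pytest.raises(ValueError):
        tr.ScoringConfig(tau=1.5)


def test_worked_example_selects_work_stress_step(example_cat):
    """A stressed-about-work post picks the work/study step and the
    work-break action over mindfulness/relationship content."""
    res = tr.suggest("Feeling stressed about my new job", example_cat)
    assert res.step == "step-work-study"
    assert res.action == "action-breathing-break"
    assert res.sentiment_class == "negative"


def test_unique_keyword_overlap_wins(lexicon):
    """With emotions identical everywhere, the only step sharing
    keywords with the post is the argmax."""
    rel = {e: 0.2 for e in EMOTIONS}
    cat = tr.Catalog(
        items=(_item("hit", keywords=("guitar", "music"), relevance=dict(rel)),
               _item("miss1", keywords=("cooking",), relevance=dict(rel)),
               _item("miss2", keywords=("gardening",), relevance=dict(rel))),
        taxonomy=tr.example_catalog().taxonomy,
        strengths=tr.example_catalog().strengths)
    res = tr.suggest("guitar music practice", cat, lexicon=lexicon)
    assert res.step == "hit"


def test_empty_catalog_yields_none(example_cat):
    cat = tr.Catalog(items=(), taxonomy=example_cat.taxonomy,
                     strengths=example_cat.strengths)
    res = tr.suggest("anything at all", cat)
    assert res.step is None and res.action is None and res.audit == ()


def test_tau_gates_low_scores(lexicon, example_cat):
    """Below-threshold maxima suppress the suggestion for that kind."""
    res = tr.suggest("zzz qqq", example_cat,
                     cfg=tr.ScoringConfig(tau=0.99), lexicon=lexicon)
    assert res.step is None and res.action is None


def test_tie_break_is_seeded_and_roughly_uniform(lexicon, example_cat):
    """Two identically scoring steps split ~50/50 across seeds, and a
    fixed seed always reproduces the same choice."""
    rel = {e: 0.5 for e in EMOTIONS}
    cat = tr.Catalog(
        items=(_item("twin-a", keywords=("work",), relevance=dict(rel)),
               _item("twin-b", keywords=("work",), relevance=dict(rel))),
        taxonomy=example_cat.taxonomy, strengths=example_cat.strengths)
    picks = Counter()
    for seed in range(400):
        res = tr.suggest("work", cat, cfg=tr.ScoringConfig(seed=seed),
                         lexicon=lexicon)
        assert res.tie_broken
        picks[res.step] += 1
    assert abs(picks["twin-a"] / 400 - 0.5) < 0.07
    one = tr.suggest("work", cat, cfg=tr.ScoringConfig(seed=42), lexicon=lexicon)
    two = tr.suggest("work", cat, cfg=tr.ScoringConfig(seed=42), lexicon=lexicon)
    assert one.step == two.step


def test_suggest_matches_brute_force_oracle(lexicon):
    """Spot-check of the engine against the independent enumeration
    oracle on randomized instances (the full 200-instance sweep lives
    in the acceptance suite)."""
    for seed in range(40):
        post, cat, cfg = make_instance(seed, lexicon)
        res = tr.suggest(post, cat, cfg=cfg, lexicon=lexicon)
        assert (res.step, res.action) == oracle_suggest(post, cat, cfg, lexicon)


def test_selected_item_never_opposes_post_valence(lexicon):
    for seed in range(40):
        post, cat, cfg = make_instance(seed, lexicon)
        res = tr.suggest(post, cat, cfg=cfg, lexicon=lexicon)
        for sel in (res.step, res.action):
            if sel is None:
                continue
            v = cat[sel].valence
            if res.sentiment_class == "positive":
                assert v != "negative"
            elif res.sentiment_class == "negative":
                assert v != "positive"


def test_equal_similarity_higher_congruence_wins(lexicon):
    """Congruence adjudicates between items with identical keyword
    similarity: the emotionally closer item scores strictly higher."""
    post_emotions = dict(zip(EMOTIONS, [0.0, 0.0, 0.6, 0.0, 0.0]))
    analysis = tr.PostAnalysis(sentiment=0.0, emotions=post_emotions,
                               keywords=("work",))
    close = _item("close", keywords=("work",),
                  relevance=dict(zip(EMOTIONS, [0.0, 0.0, 0.6, 0.0, 0.0])))
    far = _item("far", keywords=("work",),
                relevance=dict(zip(EMOTIONS, [0.9, 0.9, 0.0, 0.9, 0.9])))
    cfg = tr.ScoringConfig()
    assert (tr.score_item(analysis, close, cfg, lexicon)[2]
            > tr.score_item(analysis, far, cfg, lexicon)[2])


def test_adding_shared_keyword_never_lowers_score(lexicon):
    """Monotonicity: with congruence fixed, growing the keyword overlap
    cannot lower the combined score."""
    analysis = tr.PostAnalysis(sentiment=0.0,
                               emotions={e: 0.0 for e in EMOTIONS},
                               keywords=("work", "stress", "sleep"))
    cfg = tr.ScoringConfig()
    base = _item("a", keywords=("work",))
    more = _item("a", keywords=("work", "stress"))
    assert (tr.score_item(analysis, more, cfg, lexicon)[2]
            >= tr.score_item(analysis, base, cfg, lexicon)[2])


def test_related_steps_resolve_in_stored_order(example_cat):
    got = tr.related_steps("step-work-study", example_cat)
    assert [it.id for it in got] == ["step-mindfulness"]
    assert tr.related_steps("step-mindfulness", example_cat) == []
    with pytest.raises(tr.DomainError):
        tr.related_steps("step-ghost", example_cat)
    with pytest.raises(tr.DomainError):
        tr.related_steps("action-reach-out", example_cat)


def test_feed_action_suggestions_rank_and_exclusions(example_cat):
    profile = tr.UserProfile(user_id="u1",
                             chosen_strengths=frozenset({"Courage"}),
                             steps_taken=frozenset({"step-work-study"}))
    got = tr.feed_action_suggestions(profile, example_cat, n=3, seed=1)
    ids = [it.id for it in got]
    # breathing-break shares the Work and Study sub-tag; reach-out shares Courage
    assert set(ids) == {"action-breathing-break", "action-reach-out"}

    empty = tr.UserProfile(user_id="u2")
    assert tr.feed_action_suggestions(empty, example_cat) == []

    all_booked = tr.UserProfile(
        user_id="u3", chosen_strengths=frozenset({"Courage"}),
        bookmarked_actions=frozenset({"action-reach-out"}))
    assert tr.feed_action_suggestions(all_booked, example_cat) == []


def test_feed_action_suggestions_rank_by_shared_count(example_cat):
    """An action sharing a strength AND a sub-tag outranks one sharing
    only a strength."""
    profile = tr.UserProfile(
        user_id="u1", chosen_strengths=frozenset({"Self-Regulation", "Courage"}),
        steps_taken=frozenset({"step-work-study"}))
    got = tr.feed_action_suggestions(profile, example_cat, n=2, seed=0)
    assert got[0].id == "action-breathing-break"  # strength + sub-tag = 2


def test_strengths_page_actions(example_cat):
    profile = tr.UserProfile(user_id="u", chosen_strengths=frozenset({"Kindness"}))
    got = tr.strengths_page_actions(profile, example_cat)
    assert [it.id for it in got] == ["action-reach-out", "action-gratitude-note"]
    assert got == sorted(got, key=lambda it: it.title)
    assert tr.strengths_page_actions(tr.UserProfile(user_id="u"), example_cat) == []
    none_carry = tr.UserProfile(user_id="u", chosen_strengths=frozenset({"Humor"}))
    assert tr.strengths_page_actions(none_carry, example_cat) == []


def test_suggest_is_deterministic(lexicon):
    post, cat, cfg = make_instance(7, lexicon)
    assert (tr.suggest(post, cat, cfg=cfg, lexicon=lexicon)
            == tr.suggest(post, cat, cfg=cfg, lexicon=lexicon))
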