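"""Minimal rule-based conversational search assistant.

A deterministic slot-filling finite-state machine elicits two things —
how the user feels (mood) and what they want help with (topic) — then
routes the concatenated text through the same analyzer and suggestion
engine as a newsfeed post.  The result, together with the transcript,
forms a pre-chat profile a human moderator can review before a live
chat.  The bot is strictly a front-end: it adds no second scoring path.

Transition table (phase, input) -> next phase:

    greet,        any        -> elicit_mood
    elicit_mood,  non-blank  -> elicit_topic   (mood slot filled)
    elicit_mood,  blank      -> elicit_mood    (reprompt, max 2)
    elicit_mood,  3rd blank  -> elicit_topic   (mood slot empty)
    elicit_topic, non-blank  -> confirm        (topic slot filled)
    elicit_topic, blank      -> as above, toward confirm
    confirm,      any        -> done

Reply wording lives in a JSON template file so tone can be revised
without touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

from .catalog import Catalog
from .engine import ScoringConfig, SuggestionResult, suggest
from .errors import StateError
from .text_analysis import Lexicon, PostAnalysis, default_lexicon

PHASES = ("greet", "elicit_mood", "elicit_topic", "confirm", "done")

MAX_REPROMPTS = 2


def load_reply_templates() -> dict[str, str]:
    text = (resources.files("therapyrec.data") / "chat_replies.json").read_text("utf-8")
    return json.loads(text)


@dataclass(frozen=True)
class ChatState:
    """Immutable dialog state; ``chat_step`` returns the successor."""

    phase: str = "greet"
    mood_text: str = ""
    topic_text: str = ""
    reprompt_count: int = 0
    transcript: tuple[tuple[str, str], ...] = ()  # (speaker, text)


@dataclass(frozen=True)
class PreChatProfile:
    """Moderator-facing summary of one finished bot conversation."""

    text: str
    analysis: PostAnalysis
    suggestion: SuggestionResult
    transcript: tuple[tuple[str, str], ...]


def _advance_elicit(state: ChatState, utterance: str, slot: str,
                    next_phase: str, templates: dict[str, str],
                    next_prompt: str) -> tuple[ChatState, str]:
    text = utterance.strip()
    if text:
        new = replace(state, phase=next_phase, reprompt_count=0,
                      **{slot: text})
        return new, templates[next_prompt]
    if state.reprompt_count < MAX_REPROMPTS:
        new = replace(state, reprompt_count=state.reprompt_count + 1)
        key = "reprompt_mood" if slot == "mood_text" else "reprompt_topic"
        return new, templates[key]
    # reprompt budget exhausted: skip the phase with an empty slot
    new = replace(state, phase=next_phase, reprompt_count=0)
    return new, templates["skip"] + " " + templates[next_prompt]


def chat_step(state: ChatState, utterance: str,
              templates: dict[str, str] | None = None) -> tuple[ChatState, str]:
    """One dialog turn: consume ``utterance``, return (next state, reply).

    Deterministic; every input is handled conversationally (no errors).
    """
    templates = templates or load_reply_templates()
    if state.phase == "greet":
        new, reply = (replace(state, phase="elicit_mood"),
                      templates["greet"] + " " + templates["ask_mood"])
    elif state.phase == "elicit_mood":
        new, reply = _advance_elicit(state, utterance, "mood_text",
                                     "elicit_topic", templates, "ask_topic")
    elif state.phase == "elicit_topic":
        new, reply = _advance_elicit(state, utterance, "topic_text",
                                     "confirm", templates, "confirm")
    elif state.phase == "confirm":
        new, reply = replace(state, phase="done"), templates["done"]
    else:  # done: absorbing
        new, reply = state, templates["done"]
    new = replace(new, transcript=state.transcript + (("user", utterance),
                                                      ("bot", reply)))
    return new, reply


def run_dialog(utterances: list[str],
               templates: dict[str, str] | None = None) -> ChatState:
    """Feed a scripted list of user turns through the FSM; the dialog is
    driven to ``done`` (blank turns are appended if the script runs out)."""
    state = ChatState()
    idx = 0
    # bounded: each phase consumes at most 1 + MAX_REPROMPTS turns
    for _ in range(2 + 3 * len(PHASES)):
        if state.phase == "done":
            break
        utt = utterances[idx] if idx < len(utterances) else ""
        idx += 1
        state, _ = chat_step(state, utt, templates)
    return state


def finish_chat(state: ChatState, catalog: Catalog,
                cfg: ScoringConfig | None = None,
                lexicon: Lexicon | None = None) -> PreChatProfile:
    """Turn a finished dialog into a pre-chat profile.

    The elicited mood and topic are concatenated into a pseudo-post and
    analyzed/suggested upon exactly as a newsfeed post would be.
    """
    if state.phase != "done":
        raise StateError(f"dialog not finished (phase {state.phase!r})")
    lexicon = lexicon or default_lexicon()
    pseudo_post = (state.mood_text + " " + state.topic_text).strip()
    result = suggest(pseudo_post, catalog, cfg=cfg, lexicon=lexicon)
    return PreChatProfile(
        text=pseudo_post,
        analysis=result.analysis,
        suggestion=result,
        transcript=state.transcript,
    )
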