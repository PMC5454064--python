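"""Non-personalized content access points.

Basic text search, the alphabetical all-steps browse, and the four
"Steps People are Taking" rankings — including Hidden Treasures, which
surfaces the *least*-taken steps to counter informational cascades
(popularity begetting popularity).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

from .analytics import UsageEvent
from .catalog import Catalog, TherapyItem
from .errors import UsageError, ValidationError

DEFAULT_LIST_SIZE = 10

LINK_KINDS = ("recently_taken", "got_people_talking", "taken_most_often",
              "hidden_treasures")


@dataclass(frozen=True)
class RankedList:
    """One of the four popularity-page lists: (step id, sort key) pairs
    in display order."""

    link_kind: str
    entries: tuple[tuple[str, object], ...]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.entries)


def search(query: str, catalog: Catalog) -> list[TherapyItem]:
    """Case-insensitive substring match over title, keywords and
    sub-tags.  Title matches rank first, then keyword, then tag; ties
    alphabetical by title.  Blank queries are a usage error."""
    q = query.strip().lower()
    if not q:
        raise UsageError("search query must be non-empty")
    ranked: list[tuple[int, str, str, TherapyItem]] = []
    for it in catalog.items:
        if q in it.title.lower():
            tier = 0
        elif any(q in kw.lower() for kw in it.keywords):
            tier = 1
        elif any(q in tag.lower() for tag in it.subtags):
            tier = 2
        else:
            continue
        ranked.append((tier, it.title.lower(), it.id, it))
    ranked.sort(key=lambda t: t[:3])
    return [it for *_, it in ranked]


def all_steps(catalog: Catalog) -> list[TherapyItem]:
    """All steps, case-insensitive alphabetical by title; duplicate
    titles fall back to id order."""
    return sorted(catalog.steps, key=lambda it: (it.title.lower(), it.id))


def steps_people_are_taking(events: list[UsageEvent],
                            comments: list[tuple[str, int]],
                            catalog: Catalog,
                            k: int = DEFAULT_LIST_SIZE) -> dict[str, RankedList]:
    """Build the four "Steps People are Taking" lists from the visit log
    and the Talking Point comment-count table.

    * recently_taken — latest visit timestamp, newest first;
    * got_people_talking — Talking Point comment count, highest first;
    * taken_most_often — visit count, highest first;
    * hidden_treasures — visit count, *lowest* first, never-visited
      steps (count 0) included ahead of everything.

    Ties break by id; each list is truncated to ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    step_events = [ev for ev in events if ev.item_kind == "step"]
    bad = sorted({ev.item_id for ev in step_events if ev.item_id not in catalog})
    bad += sorted({sid for sid, _ in comments if sid not in catalog})
    if bad:
        raise ValidationError([f"event/comment references unknown step {b!r}" for b in bad])

    counts: dict[str, int] = {}
    latest: dict[str, datetime] = {}
    for ev in step_events:
        counts[ev.item_id] = counts.get(ev.item_id, 0) + 1
        ts = ev.timestamp
        if ev.item_id not in latest or ts > latest[ev.item_id]:
            latest[ev.item_id] = ts

    recent = sorted(latest.items(), key=lambda t: (t[1], t[0]))
    recent = sorted(recent, key=lambda t: t[1], reverse=True)
    talking = sorted(((sid, c) for sid, c in comments), key=lambda t: (-t[1], t[0]))
    often = sorted(counts.items(), key=lambda t: (-t[1], t[0]))
    treasures = sorted(
        ((st.id, counts.get(st.id, 0)) for st in catalog.steps),
        key=lambda t: (t[1], t[0]),
    )

    def _mk(kind: str, pairs) -> RankedList:
        return RankedList(link_kind=kind, entries=tuple(pairs[:k]))

    return {
        "recently_taken": _mk("recently_taken", recent),
        "got_people_talking": _mk("got_people_talking", talking),
        "taken_most_often": _mk("taken_most_often", often),
        "hidden_treasures": _mk("hidden_treasures", treasures),
    }
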