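"""Therapy-content catalog: data model, validation and JSON file I/O.

A catalog bundles three things:

* a tag taxonomy — parent tags, each with sub-tags, used to categorise
  content by symptom group or skill;
* the canonical list of character strengths from which each user picks
  five during onboarding;
* the therapy items themselves — *steps* (interactive therapy modules)
  and *actions* (real-world behavioural tasks), each carrying a valence
  class, a five-emotion relevance vector, keywords, sub-tags and, for
  actions, the strengths they exercise.

Validation is collect-all: loading reports every violation at once
rather than stopping at the first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import CatalogFormatError, DomainError, ValidationError

EMOTIONS: tuple[str, ...] = ("anger", "disgust", "fear", "joy", "sadness")

VALENCES: tuple[str, ...] = ("positive", "negative", "either")

KINDS: tuple[str, ...] = ("step", "action")


@dataclass(frozen=True)
class TagTaxonomy:
    """Parent tags and their sub-tags.

    The canonical taxonomy has three parents (Coping, Connecting,
    Enhancing) with three sub-tags each; arbitrary taxonomies are
    permitted as long as every sub-tag has exactly one parent and
    sub-tag names are globally unique.
    """

    parents: tuple[str, ...]
    children: dict[str, tuple[str, ...]]

    def subtags(self) -> tuple[str, ...]:
        out: list[str] = []
        for p in self.parents:
            out.extend(self.children.get(p, ()))
        return tuple(out)

    def validate(self) -> list[str]:
        problems = []
        if set(self.children) != set(self.parents):
            problems.append("taxonomy: children keys must equal parent list")
        seen: set[str] = set()
        for p in self.parents:
            for s in self.children.get(p, ()):
                if s in seen:
                    problems.append(f"taxonomy: sub-tag {s!r} appears under more than one parent")
                seen.add(s)
        return problems


@dataclass(frozen=True)
class TherapyItem:
    """One step or action.

    ``emotion_relevance`` maps each of the five emotions to [0, 1]; the
    higher the value the more relevant the item is for posts exhibiting
    that emotion.  ``valence`` says which sentiment class of post the
    item suits: ``positive``, ``negative`` or ``either``.
    """

    id: str
    kind: str
    title: str
    valence: str
    emotion_relevance: dict[str, float]
    keywords: frozenset[str]
    subtags: frozenset[str]
    strengths: frozenset[str] = frozenset()
    related_ids: tuple[str, ...] = ()

    def to_record(self) -> dict:
        return {
            "id": self.id,
            "kind": self.kind,
            "title": self.title,
            "valence": self.valence,
            "emotion_relevance": {e: self.emotion_relevance[e] for e in EMOTIONS},
            "keywords": sorted(self.keywords),
            "subtags": sorted(self.subtags),
            "strengths": sorted(self.strengths),
            "related_ids": list(self.related_ids),
        }


@dataclass(frozen=True)
class Catalog:
    """A validated collection of therapy items plus taxonomy and strengths."""

    items: tuple[TherapyItem, ...]
    taxonomy: TagTaxonomy
    strengths: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "_by_id", {it.id: it for it in self.items})

    def __getitem__(self, item_id: str) -> TherapyItem:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise DomainError(f"unknown item id {item_id!r}") from None

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    @property
    def steps(self) -> tuple[TherapyItem, ...]:
        return tuple(it for it in self.items if it.kind == "step")

    @property
    def actions(self) -> tuple[TherapyItem, ...]:
        return tuple(it for it in self.items if it.kind == "action")


def _validate_item(rec: TherapyItem, taxonomy: TagTaxonomy,
                   strengths: Iterable[str], step_ids: set[str]) -> list[str]:
    problems = []
    where = f"item {rec.id!r}"
    if rec.kind not in KINDS:
        problems.append(f"{where}: kind {rec.kind!r} not in {KINDS}")
    if rec.valence not in VALENCES:
        problems.append(f"{where}: valence {rec.valence!r} not in {VALENCES}")
    if set(rec.emotion_relevance) != set(EMOTIONS):
        problems.append(f"{where}: emotion_relevance keys must be exactly {set(EMOTIONS)}")
    for e, v in rec.emotion_relevance.items():
        if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
            problems.append(
                f"{where}: emotion_relevance[{e!r}] = {v!r} outside the unit interval [0,1]"
            )
    if not rec.keywords:
        problems.append(f"{where}: keywords must be non-empty")
    if not rec.subtags:
        problems.append(f"{where}: subtags must be non-empty")
    unknown_tags = rec.subtags - set(taxonomy.subtags())
    for t in sorted(unknown_tags):
        problems.append(f"{where}: sub-tag {t!r} not in taxonomy")
    unknown_str = rec.strengths - set(strengths)
    for s in sorted(unknown_str):
        problems.append(f"{where}: strength {s!r} not in canonical strengths")
    if rec.kind == "action" and rec.related_ids:
        problems.append(f"{where}: related_ids are only allowed on steps")
    for rid in rec.related_ids:
        if rid not in step_ids:
            problems.append(f"{where}: related_id {rid!r} is a dangling step reference")
    return problems


def validate_catalog(catalog: Catalog) -> list[str]:
    """Return every invariant violation in ``catalog`` (empty = valid)."""
    problems = catalog.taxonomy.validate()
    if len(set(catalog.strengths)) != len(catalog.strengths):
        problems.append("strengths list contains duplicates")
    seen_ids: set[str] = set()
    for it in catalog.items:
        if it.id in seen_ids:
            problems.append(f"duplicate item id {it.id!r}")
        seen_ids.add(it.id)
    step_ids = {it.id for it in catalog.items if it.kind == "step"}
    for it in catalog.items:
        problems.extend(_validate_item(it, catalog.taxonomy, catalog.strengths, step_ids))
    return problems


def _item_from_record(rec: dict, idx: int) -> TherapyItem:
    try:
        return TherapyItem(
            id=str(rec["id"]),
            kind=str(rec["kind"]),
            title=str(rec["title"]),
            valence=str(rec["valence"]),
            emotion_relevance={str(k): v for k, v in rec["emotion_relevance"].items()},
            keywords=frozenset(str(k) for k in rec["keywords"]),
            subtags=frozenset(str(t) for t in rec["subtags"]),
            strengths=frozenset(str(s) for s in rec.get("strengths", [])),
            related_ids=tuple(str(r) for r in rec.get("related_ids", [])),
        )
    except (KeyError, TypeError, AttributeError) as exc:
        raise CatalogFormatError(f"item record #{idx}: malformed ({exc!r})") from exc


def catalog_from_dict(doc: dict) -> Catalog:
    """Build and validate a :class:`Catalog` from a parsed JSON document."""
    for key in ("taxonomy", "strengths", "items"):
        if key not in doc:
            raise CatalogFormatError(f"catalog document missing top-level key {key!r}")
    tax = doc["taxonomy"]
    try:
        taxonomy = TagTaxonomy(
            parents=tuple(str(p) for p in tax["parents"]),
            children={str(p): tuple(str(c) for c in cs) for p, cs in tax["children"].items()},
        )
    except (KeyError, TypeError, AttributeError) as exc:
        raise CatalogFormatError(f"taxonomy block malformed ({exc!r})") from exc
    items = tuple(_item_from_record(rec, i) for i, rec in enumerate(doc["items"]))
    catalog = Catalog(items=items, taxonomy=taxonomy,
                      strengths=tuple(str(s) for s in doc["strengths"]))
    problems = validate_catalog(catalog)
    if problems:
        raise ValidationError(problems)
    return catalog


def load_catalog(path: str | Path) -> Catalog:
    """Load and validate a catalog from a UTF-8 JSON file.

    Raises :class:`CatalogFormatError` on parse failure (naming the
    line) and :class:`ValidationError` listing *every* invariant
    violation otherwise.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CatalogFormatError(
            f"{path}: not valid JSON (line {exc.lineno}, column {exc.colno}: {exc.msg})"
        ) from exc
    return catalog_from_dict(doc)


def catalog_to_dict(catalog: Catalog) -> dict:
    return {
        "taxonomy": {
            "parents": list(catalog.taxonomy.parents),
            "children": {p: list(cs) for p, cs in catalog.taxonomy.children.items()},
        },
        "strengths": list(catalog.strengths),
        "items": [it.to_record() for it in catalog.items],
    }


def save_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write ``catalog`` as UTF-8 JSON; ``load_catalog`` round-trips it."""
    Path(path).write_text(
        json.dumps(catalog_to_dict(catalog), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


@dataclass(frozen=True)
class SelectionVerdict:
    """Outcome of validating a user's strength selection."""

    accepted: bool
    reasons: tuple[str, ...] = ()


STRENGTH_SELECTION_SIZE = 5


def validate_strength_selection(chosen: Iterable[str], catalog: Catalog) -> SelectionVerdict:
    """Accept iff ``chosen`` is exactly five distinct canonical strengths.

    Invalid selections are rejected with reasons; this never raises.
    """
    chosen = list(chosen)
    reasons: list[str] = []
    distinct = set(chosen)
    if len(chosen) != len(distinct):
        reasons.append("duplicate strength names")
    if len(distinct) != STRENGTH_SELECTION_SIZE:
        reasons.append(
            f"cardinality: expected exactly {STRENGTH_SELECTION_SIZE} distinct "
            f"strengths, got {len(distinct)}"
        )
    for name in sorted(distinct - set(catalog.strengths)):
        reasons.append(f"unknown strength: {name!r}")
    return SelectionVerdict(accepted=not reasons, reasons=tuple(reasons))


def items_by_subtag(catalog: Catalog, subtag: str) -> list[TherapyItem]:
    """All items tagged with ``subtag``, sorted by title.

    Raises :class:`DomainError` if the sub-tag is not in the taxonomy.
    """
    if subtag not in catalog.taxonomy.subtags():
        raise DomainError(f"unknown sub-tag {subtag!r}")
    hits = [it for it in catalog.items if subtag in it.subtags]
    return sorted(hits, key=lambda it: (it.title, it.id))
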