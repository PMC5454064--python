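"""Engagement accounting over usage-event logs and the moderator
suggestion ledger.

Every visit to a step or action is tracked with the access path that
led to it (search, menu, a popularity link, a moderator suggestion, a
post-triggered suggestion, ...).  Moderator suggestions additionally
live in a ledger whose entries end in one of four outcomes: completed,
client-dismissed, moderator-dismissed, or still pending.

Both logs are plain CSV (header row, comma-separated, ISO-8601
timestamps); round-tripping preserves counts per (path, kind).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

from .errors import UsageError, ValidationError

ACCESS_PATHS = (
    "search", "menu", "tag_browse",
    "steps_recent", "steps_talking", "steps_often", "hidden_treasures",
    "strengths_page", "moderator_suggestion", "related_after_step",
    "newsfeed_suggestion", "post_suggestion", "other",
)

FOUR_LINK_PATHS = ("steps_recent", "steps_talking", "steps_often",
                   "hidden_treasures")

SUGGESTION_STATUSES = ("pending", "completed", "client_dismissed",
                       "moderator_dismissed")


@dataclass(frozen=True)
class UsageEvent:
    """One tracked visit to a step or action."""

    user_id: str
    item_id: str
    item_kind: str  # "step" | "action"
    access_path: str
    timestamp: datetime


@dataclass(frozen=True)
class SuggestionRecord:
    """One moderator-to-user content suggestion and its outcome."""

    record_id: str
    moderator_id: str
    user_id: str
    item_id: str
    status: str


@dataclass(frozen=True)
class OutcomeSummary:
    """Status tally over a suggestion ledger; counts partition the total."""

    total: int
    counts: dict[str, int]
    completion_fraction: float


# ---------------------------------------------------------------------------
# CSV I/O

_EVENT_FIELDS = ("user_id", "item_id", "item_kind", "access_path", "timestamp")
_LEDGER_FIELDS = ("record_id", "moderator_id", "user_id", "item_id", "status")


def read_events(path: str | Path) -> list[UsageEvent]:
    """Read a usage-event CSV, validating paths, kinds and timestamps.

    All malformed rows are reported together in one ValidationError.
    """
    events: list[UsageEvent] = []
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_EVENT_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError([f"event log missing column(s) {sorted(missing)}"])
        for lineno, row in enumerate(reader, start=2):
            path_val = row["access_path"].strip()
            kind = row["item_kind"].strip()
            if path_val not in ACCESS_PATHS:
                problems.append(f"line {lineno}: unknown access_path {path_val!r}")
            if kind not in ("step", "action"):
                problems.append(f"line {lineno}: unknown item_kind {kind!r}")
            try:
                ts = datetime.fromisoformat(row["timestamp"].strip())
            except ValueError:
                problems.append(f"line {lineno}: unparseable timestamp {row['timestamp']!r}")
                continue
            events.append(UsageEvent(
                user_id=row["user_id"].strip(), item_id=row["item_id"].strip(),
                item_kind=kind, access_path=path_val, timestamp=ts,
            ))
    if problems:
        raise ValidationError(problems)
    return events


def write_events(events: list[UsageEvent], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EVENT_FIELDS)
        for ev in events:
            writer.writerow([ev.user_id, ev.item_id, ev.item_kind,
                             ev.access_path, ev.timestamp.isoformat()])


def read_ledger(path: str | Path) -> list[SuggestionRecord]:
    """Read a moderator-suggestion ledger CSV; unknown statuses are
    collected into one ValidationError."""
    records: list[SuggestionRecord] = []
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_LEDGER_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError([f"ledger missing column(s) {sorted(missing)}"])
        for lineno, row in enumerate(reader, start=2):
            status = row["status"].strip()
            if status not in SUGGESTION_STATUSES:
                problems.append(f"line {lineno}: unknown status {status!r}")
                continue
            records.append(SuggestionRecord(
                record_id=row["record_id"].strip(),
                moderator_id=row["moderator_id"].strip(),
                user_id=row["user_id"].strip(),
                item_id=row["item_id"].strip(),
                status=status,
            ))
    if problems:
        raise ValidationError(problems)
    return records


def write_ledger(records: list[SuggestionRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LEDGER_FIELDS)
        for rec in records:
            writer.writerow([rec.record_id, rec.moderator_id, rec.user_id,
                             rec.item_id, rec.status])


# ---------------------------------------------------------------------------
# summaries


def suggestion_outcomes(ledger: list[SuggestionRecord]) -> OutcomeSummary:
    """Tally ledger outcomes; counts always sum to the ledger size and
    the completion fraction is completed/total (0 on an empty ledger)."""
    counts = {s: 0 for s in SUGGESTION_STATUSES}
    for rec in ledger:
        if rec.status not in counts:
            raise ValidationError([f"record {rec.record_id!r}: unknown status {rec.status!r}"])
        counts[rec.status] += 1
    total = len(ledger)
    frac = counts["completed"] / total if total else 0.0
    return OutcomeSummary(total=total, counts=counts, completion_fraction=frac)


def four_link_share(events: list[UsageEvent]) -> dict[str, dict[str, float]]:
    """Visit share of each of the four "Steps People are Taking" links,
    among visits arriving through any of the four.

    Returns per path: exact percentage (``percent``) and its nearest
    integer (``percent_int``).  Raises UsageError when no event used
    any of the four links (undefined denominator).
    """
    counts = {p: 0 for p in FOUR_LINK_PATHS}
    for ev in events:
        if ev.access_path in counts:
            counts[ev.access_path] += 1
    denom = sum(counts.values())
    if denom == 0:
        raise UsageError("no events arrived via the four popularity links; share undefined")
    return {
        p: {"count": counts[p],
            "percent": 100.0 * counts[p] / denom,
            "percent_int": round(100.0 * counts[p] / denom)}
        for p in FOUR_LINK_PATHS
    }


def tracked_visit_share(events: list[UsageEvent], path: str,
                        kind: str = "both") -> float:
    """Percentage of all tracked visits that arrived via ``path``.

    ``kind`` restricts the denominator (and numerator) to "step" or
    "action" visits; the default "both" uses every tracked visit.
    """
    if path not in ACCESS_PATHS:
        raise UsageError(f"unknown access path {path!r}")
    if kind not in ("step", "action", "both"):
        raise UsageError(f"kind must be step, action or both, got {kind!r}")
    pool = [ev for ev in events if kind == "both" or ev.item_kind == kind]
    if not pool:
        raise UsageError("no tracked events; share undefined")
    return 100.0 * sum(1 for ev in pool if ev.access_path == path) / len(pool)
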