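"""Deterministic lexicon-based text analysis of user posts.

Produces, for one free-text post: a sentiment score in [-1, 1] (0 is
neutral, positive values positive, negative values negative), a score
in [0, 1] for each of the five emotions anger, disgust, fear, joy and
sadness, and a ranked keyword list.  This local analyzer keeps the
suggestion pipeline fully reproducible and network-free; any backend
returning a valid :class:`PostAnalysis` can be substituted.

Scoring rules
-------------
* sentiment: mean valence of lexicon-matched tokens, a negator
  ("not", "no", "never" or any token ending in "n't") flipping the
  sign of the immediately following matched token; clipped to [-1, 1];
  no match at all scores exactly 0.
* emotion e: (content tokens carrying e) / max(1, content tokens),
  where content tokens are the non-stopword tokens — an emotional
  *density*, bounded and monotone in emotional-token share.
* keywords: content tokens ranked by frequency, ties broken by first
  occurrence, truncated to k (default 10).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .catalog import EMOTIONS
from .errors import CatalogFormatError

DEFAULT_KEYWORD_COUNT = 10

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")


@dataclass(frozen=True)
class Lexicon:
    """Token -> (valence, emotion memberships) mapping plus stopword and
    negator lists.  All tokens are lowercase; valences lie in [-1, 1]."""

    entries: dict[str, tuple[float, frozenset[str]]]
    negators: frozenset[str]
    stopwords: frozenset[str]

    def valence(self, token: str) -> float | None:
        entry = self.entries.get(token)
        return entry[0] if entry is not None else None

    def emotions_of(self, token: str) -> frozenset[str]:
        entry = self.entries.get(token)
        return entry[1] if entry is not None else frozenset()

    def is_negator(self, token: str) -> bool:
        return token in self.negators or token.endswith("n't")


@dataclass(frozen=True)
class PostAnalysis:
    """Linguistic summary of one post."""

    sentiment: float
    emotions: dict[str, float]
    keywords: tuple[str, ...]

    @property
    def sentiment_class(self) -> str:
        if self.sentiment > 0:
            return "positive"
        if self.sentiment < 0:
            return "negative"
        return "neutral"


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens; punctuation stripped, apostrophes kept
    inside words ("can't" stays one token)."""
    return _TOKEN_RE.findall(text.lower())


def content_tokens(tokens: list[str], lexicon: Lexicon) -> list[str]:
    return [t for t in tokens if t not in lexicon.stopwords]


def sentiment_score(tokens: list[str], lexicon: Lexicon) -> float:
    """Clipped mean of matched token valences with 1-token negation."""
    matched: list[float] = []
    negate_next = False
    for tok in tokens:
        v = lexicon.valence(tok)
        if v is not None:
            matched.append(-v if negate_next else v)
            negate_next = False
        else:
            # a negator arms sign-flipping for the next matched token only
            negate_next = lexicon.is_negator(tok)
    if not matched:
        return 0.0
    return max(-1.0, min(1.0, sum(matched) / len(matched)))


def emotion_scores(tokens: list[str], lexicon: Lexicon) -> dict[str, float]:
    """Density of each emotion among content tokens, each in [0, 1]."""
    content = content_tokens(tokens, lexicon)
    denom = max(1, len(content))
    scores = {}
    for e in EMOTIONS:
        n = sum(1 for t in content if e in lexicon.emotions_of(t))
        scores[e] = max(0.0, min(1.0, n / denom))
    return scores


def extract_keywords(tokens: list[str], lexicon: Lexicon,
                     k: int = DEFAULT_KEYWORD_COUNT) -> list[str]:
    """Top-k content tokens by frequency; ties go to the earlier first
    occurrence; duplicate-free."""
    if k < 1:
        raise ValueError("k must be >= 1")
    content = content_tokens(tokens, lexicon)
    first_pos: dict[str, int] = {}
    counts: dict[str, int] = {}
    for i, t in enumerate(content):
        counts[t] = counts.get(t, 0) + 1
        first_pos.setdefault(t, i)
    ranked = sorted(counts, key=lambda t: (-counts[t], first_pos[t]))
    return ranked[:k]


def analyze_post(text: str, lexicon: Lexicon,
                 k: int = DEFAULT_KEYWORD_COUNT) -> PostAnalysis:
    """Full analysis of one post; deterministic in (text, lexicon, k)."""
    tokens = tokenize(text)
    return PostAnalysis(
        sentiment=sentiment_score(tokens, lexicon),
        emotions=emotion_scores(tokens, lexicon),
        keywords=tuple(extract_keywords(tokens, lexicon, k)),
    )


# ---------------------------------------------------------------------------
# lexicon file I/O
#
# Lexicon format: one entry per line, `token<TAB>valence<TAB>em1;em2`,
# the third column empty for emotion-free tokens.  Stopwords and
# negators are plain one-token-per-line files.


def _parse_lexicon_entries(text: str, source: str) -> dict[str, tuple[float, frozenset[str]]]:
    entries: dict[str, tuple[float, frozenset[str]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise CatalogFormatError(
                f"{source}:{lineno}: expected 2-3 tab-separated fields, got {len(parts)}"
            )
        token = parts[0].strip().lower()
        try:
            valence = float(parts[1])
        except ValueError:
            raise CatalogFormatError(
                f"{source}:{lineno}: valence {parts[1]!r} is not a number"
            ) from None
        if not -1.0 <= valence <= 1.0:
            raise CatalogFormatError(
                f"{source}:{lineno}: valence {valence} outside [-1, 1]"
            )
        emo_field = parts[2].strip() if len(parts) == 3 else ""
        emotions = frozenset(e.strip() for e in emo_field.split(";") if e.strip())
        bad = emotions - set(EMOTIONS)
        if bad:
            raise CatalogFormatError(
                f"{source}:{lineno}: unknown emotion(s) {sorted(bad)}"
            )
        entries[token] = (valence, emotions)
    return entries


def _parse_wordlist(text: str) -> frozenset[str]:
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )


def load_lexicon(entries_path: str | Path,
                 stopwords_path: str | Path | None = None,
                 negators_path: str | Path | None = None) -> Lexicon:
    """Load a lexicon from delimited-text files (UTF-8)."""
    entries = _parse_lexicon_entries(
        Path(entries_path).read_text(encoding="utf-8"), str(entries_path))
    stop = (_parse_wordlist(Path(stopwords_path).read_text(encoding="utf-8"))
            if stopwords_path else frozenset())
    neg = (_parse_wordlist(Path(negators_path).read_text(encoding="utf-8"))
           if negators_path else frozenset({"not", "no", "never"}))
    return Lexicon(entries=entries, negators=neg, stopwords=stop)


def default_lexicon() -> Lexicon:
    """The small lexicon bundled with the package."""
    pkg = resources.files("therapyrec.data")
    entries = _parse_lexicon_entries(
        (pkg / "lexicon.tsv").read_text(encoding="utf-8"), "lexicon.tsv")
    stop = _parse_wordlist((pkg / "stopwords.txt").read_text(encoding="utf-8"))
    neg = _parse_wordlist((pkg / "negators.txt").read_text(encoding="utf-8"))
    return Lexicon(entries=entries, negators=neg, stopwords=stop)
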