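"""Continuous concreteness scoring for headlines.

Pipeline per headline: entity detection on the original-cased text; token
filtering (stopwords removed except forward references and pronouns,
punctuation and cardinal numbers ignored); iterative morphological fallback
against the lexicon; arithmetic mean over all component ratings, with
entities pinned at the ceiling rating of 5.  A headline containing an
unresolvable word of three or more letters is excluded rather than scored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import morphology
from .lexicon import Lexicon
from .ner import EntitySpan, detect_entities
from .stopwords import DEFAULT_RETAINED, ENGLISH_STOPWORDS

ENTITY_RATING = 5.0

SOURCE_ENTITY = "entity"
SOURCE_DIRECT = "direct"
SOURCE_SINGULARIZED = "singularized"
SOURCE_PRESENT_TENSE = "present_tense"
SOURCE_BASE_ADJECTIVE = "base_adjective"
SOURCE_HYPHEN_AVERAGE = "hyphen_average"

EXCLUDED_NONE = "none"
EXCLUDED_UNMATCHED = "unmatched_long_word"
EXCLUDED_EMPTY = "no_scoreable_tokens"

_WORD_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'’\-]*")
_CARDINAL_RE = re.compile(r"^[\d][\d,.]*$")
_POSSESSIVE_RE = re.compile(r"['’]s$")


@dataclass(frozen=True)
class Candidate:
    """A scoreable unit emitted by tokenization: a word or an entity span."""

    text: str
    is_entity: bool = False


@dataclass(frozen=True)
class TokenScore:
    surface: str
    resolved_form: str
    source: str
    rating: float

    def __post_init__(self) -> None:
        if self.source == SOURCE_ENTITY and self.rating != ENTITY_RATING:
            raise ValueError("entity components must carry the ceiling rating")
        if not (0.0 <= self.rating <= 5.0):
            raise ValueError(f"rating {self.rating} outside [0, 5]")


@dataclass
class HeadlineScore:
    headline: str
    components: list[TokenScore] = field(default_factory=list)
    value: float | None = None
    excluded: bool = False
    exclusion_reason: str = EXCLUDED_NONE


def tokenize_and_filter(
    headline: str,
    entity_spans: Sequence[EntitySpan],
    retained_stopwords: Iterable[str] = DEFAULT_RETAINED,
    stopwords: Iterable[str] = ENGLISH_STOPWORDS,
) -> list[Candidate]:
    """Split a headline into scoreable candidates.

    Entity spans (from :func:`headconc.ner.detect_entities` on the same text)
    become single entity candidates; remaining text is tokenized, case-folded,
    and filtered of punctuation, cardinal numbers, and stopwords — except for
    the retained forward-reference/pronoun list.
    """
    retained = {w.lower() for w in retained_stopwords}
    stop = {w.lower() for w in stopwords}
    spans = sorted(entity_spans, key=lambda s: s.start)
    candidates: list[Candidate] = []
    cursor = 0
    segments: list[tuple[str, EntitySpan | None]] = []
    for span in spans:
        segments.append((headline[cursor : span.start], None))
        segments.append((headline[span.start : span.end], span))
        cursor = span.end
    segments.append((headline[cursor:], None))

    for seg_text, span in segments:
        if span is not None:
            candidates.append(Candidate(span.text, is_entity=True))
            continue
        for m in _WORD_RE.finditer(seg_text):
            tok = _POSSESSIVE_RE.sub("", m.group(0).lower()).strip("'’-")
            if not tok or _CARDINAL_RE.match(tok):
                continue
            if tok in stop and tok not in retained:
                continue
            candidates.append(Candidate(tok))
    return candidates


def resolve_token(token: str, lexicon: Lexicon) -> TokenScore | None:
    """Map a non-entity token to a rating via the iterative fallback chain.

    Order: direct lookup, singular form, present-tense form, base adjective;
    then, for hyphenated tokens, the average of both halves resolved by the
    same chain.  Returns ``None`` when every step fails.
    """
    direct = lexicon.lookup(token)
    if direct is not None:
        return TokenScore(token, token, SOURCE_DIRECT, direct)
    for source, candidates in (
        (SOURCE_SINGULARIZED, morphology.singular_candidates(token)),
        (SOURCE_PRESENT_TENSE, morphology.present_candidates(token)),
        (SOURCE_BASE_ADJECTIVE, morphology.adjective_candidates(token)),
    ):
        for form in candidates:
            rating = lexicon.lookup(form)
            if rating is not None:
                return TokenScore(token, form, source, rating)
    if "-" in token:
        halves = [h for h in token.split("-") if h]
        if len(halves) == 2:
            resolved = [resolve_token(h, lexicon) for h in halves]
            if all(r is not None for r in resolved):
                mean = sum(r.rating for r in resolved) / 2.0  # type: ignore[union-attr]
                return TokenScore(token, " ".join(halves), SOURCE_HYPHEN_AVERAGE, mean)
    return None


def _letter_count(token: str) -> int:
    return sum(ch.isalpha() for ch in token)


def score_headline(
    headline: str,
    lexicon: Lexicon,
    ner_backend: str = "rule",
    retained_stopwords: Iterable[str] = DEFAULT_RETAINED,
) -> HeadlineScore:
    """Score one headline; entities rate 5, words via the fallback chain.

    An unresolved token with >= 3 letters excludes the headline
    (``unmatched_long_word``); shorter unresolved tokens are dropped.  A
    headline with no scoreable candidates is excluded
    (``no_scoreable_tokens``).
    """
    if not headline or not headline.strip():
        raise ValueError("headline must be non-empty")
    spans = detect_entities(headline, backend=ner_backend)
    candidates = tokenize_and_filter(headline, spans, retained_stopwords=retained_stopwords)
    result = HeadlineScore(headline=headline)
    for cand in candidates:
        if cand.is_entity:
            result.components.append(
                TokenScore(cand.text, cand.text, SOURCE_ENTITY, ENTITY_RATING)
            )
            continue
        score = resolve_token(cand.text, lexicon)
        if score is not None:
            result.components.append(score)
        elif _letter_count(cand.text) >= 3:
            result.excluded = True
            result.exclusion_reason = EXCLUDED_UNMATCHED
            result.components = []
            result.value = None
            return result
        # unresolved tokens with <= 2 letters are silently dropped
    if not result.components:
        result.excluded = True
        result.exclusion_reason = EXCLUDED_EMPTY
        result.value = None
        return result
    result.value = sum(c.rating for c in result.components) / len(result.components)
    return result


def score_corpus(
    table: pd.DataFrame,
    lexicon: Lexicon,
    headline_column: str = "headline",
    ner_backend: str = "rule",
    retained_stopwords: Iterable[str] = DEFAULT_RETAINED,
) -> tuple[pd.DataFrame, dict]:
    """Score every row of a headline table.

    Returns a table with columns ``headline, score, excluded,
    exclusion_reason, n_components`` plus a summary of exclusion counts and
    fractions by reason.  Identical headline strings get identical scores
    (memoized).
    """
    if headline_column not in table.columns:
        raise KeyError(f"missing headline column {headline_column!r}")
    cache: dict[str, HeadlineScore] = {}
    rows = []
    for text in table[headline_column].astype(str):
        hs = cache.get(text)
        if hs is None:
            hs = score_headline(
                text, lexicon, ner_backend=ner_backend, retained_stopwords=retained_stopwords
            )
            cache[text] = hs
        rows.append(
            (text, hs.value, hs.excluded, hs.exclusion_reason, len(hs.components))
        )
    out = pd.DataFrame(
        rows, columns=["headline", "score", "excluded", "exclusion_reason", "n_components"]
    )
    n = len(out)
    by_reason = (
        out.loc[out["excluded"], "exclusion_reason"].value_counts().to_dict()
    )
    summary = {
        "n_headlines": n,
        "n_excluded": int(out["excluded"].sum()),
        "fraction_excluded": float(out["excluded"].mean()) if n else 0.0,
        "excluded_by_reason": by_reason,
    }
    return out, summary
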