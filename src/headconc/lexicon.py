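"""Word-level concreteness lexicon: loading, validation, and lookup.

The lexicon maps lowercase word forms (and occasional bigrams) to a mean
concreteness rating on the closed interval [0, 5].  Lookup of an absent word
returns ``None`` — absence is a value, never a default rating.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

RATING_MIN = 0.0
RATING_MAX = 5.0

#: Column names of the published word-ratings file dialect.
DEFAULT_WORD_COLUMN = "Word"
DEFAULT_RATING_COLUMN = "Conc.M"


class LexiconError(ValueError):
    """Malformed or unusable lexicon input."""


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    rating: float

    def __post_init__(self) -> None:
        if not self.word:
            raise ValueError("word must be non-empty")
        if self.word != self.word.lower():
            raise ValueError("word must be stored case-folded")
        if not (math.isfinite(self.rating) and RATING_MIN <= self.rating <= RATING_MAX):
            raise ValueError(f"rating {self.rating!r} outside [{RATING_MIN}, {RATING_MAX}]")


@dataclass
class Lexicon:
    """Immutable-by-convention mapping of word form -> concreteness rating."""

    _entries: dict[str, float] = field(default_factory=dict)
    n_rejected: int = 0

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "Lexicon":
        entries: dict[str, float] = {}
        for word, rating in mapping.items():
            e = LexiconEntry(str(word).lower(), float(rating))
            entries[e.word] = e.rating
        return cls(entries)

    def lookup(self, word: str) -> float | None:
        """Case-folded exact-match lookup; ``None`` if absent."""
        if not word:
            raise ValueError("word must be non-empty")
        return self._entries.get(word.lower())

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    @property
    def min_rating(self) -> float:
        if not self._entries:
            raise LexiconError("empty lexicon has no minimum rating")
        return min(self._entries.values())

    def items(self):
        return self._entries.items()


def load_lexicon(
    path: str | Path,
    word_column: str = DEFAULT_WORD_COLUMN,
    rating_column: str = DEFAULT_RATING_COLUMN,
    delimiter: str | None = None,
) -> Lexicon:
    """Load a delimited ratings file (comma or tab; sniffed when not given).

    Rows with unparseable ratings or ratings outside [0, 5] are rejected and
    counted (``Lexicon.n_rejected``) with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import csv

    try:
        df = pd.read_csv(path, sep=delimiter, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        raise LexiconError(f"{path}: zero parseable rows") from None
    for col in (word_column, rating_column):
        if col not in df.columns:
            raise LexiconError(f"{path}: missing column {col!r} (have {list(df.columns)})")

    ratings = pd.to_numeric(df[rating_column], errors="coerce")
    words = df[word_column].astype(str).str.strip().str.lower()
    ok = (
        ratings.notna()
        & (ratings >= RATING_MIN)
        & (ratings <= RATING_MAX)
        & (words != "")
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: rejected %d rows (unparseable or out-of-range ratings)", path, n_rejected)
    entries = dict(zip(words[ok], ratings[ok].astype(float)))
    if not entries:
        raise LexiconError(f"{path}: zero parseable rows")
    lex = Lexicon(entries)
    lex.n_rejected = n_rejected
    return lex


def write_lexicon(
    lexicon: Lexicon,
    path: str | Path,
    word_column: str = DEFAULT_WORD_COLUMN,
    rating_column: str = DEFAULT_RATING_COLUMN,
    delimiter: str = ",",
) -> None:
    """Write the lexicon in the configured delimited dialect (round-trips)."""
    df = pd.DataFrame(sorted(lexicon.items()), columns=[word_column, rating_column])
    df.to_csv(path, sep=delimiter, index=False)
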