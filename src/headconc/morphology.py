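"""Deterministic rule-based inflection candidates.

Each function returns an ordered list of candidate base forms for a token;
the caller re-queries the lexicon after each candidate, stopping at the
first hit.  Rules are intentionally simple and reproducible — no statistical
lemmatizer is involved.
"""

from __future__ import annotations

_IRREGULAR_PLURALS = {
    "men": "man",
    "women": "woman",
    "children": "child",
    "people": "person",
    "feet": "foot",
    "teeth": "tooth",
    "mice": "mouse",
    "geese": "goose",
    "wives": "wife",
    "lives": "life",
    "knives": "knife",
    "leaves": "leaf",
    "selves": "self",
}

_VOWELS = set("aeiou")


def _undouble(stem: str) -> str | None:
    # "stopp" -> "stop"; only for a doubled final consonant.
    if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
        return stem[:-1]
    return None


def singular_candidates(token: str) -> list[str]:
    """Candidate singular forms, most specific rule first."""
    out: list[str] = []
    if token in _IRREGULAR_PLURALS:
        out.append(_IRREGULAR_PLURALS[token])
    if token.endswith("ies") and len(token) > 4:
        out.append(token[:-3] + "y")
    if token.endswith("ves") and len(token) > 4:
        out.extend([token[:-3] + "f", token[:-3] + "fe"])
    if token.endswith("es") and len(token) > 3:
        if token[-3] in "sxz" or token[-4:-2] in ("ch", "sh"):
            out.append(token[:-2])
        out.append(token[:-1])  # e.g. "heroes" -> "heroe" fails, "cases" -> "case"
        out.append(token[:-2])
    if token.endswith("s") and not token.endswith("ss") and len(token) > 2:
        out.append(token[:-1])
    return _dedupe(out, token)


def present_candidates(token: str) -> list[str]:
    """Candidate present-tense verb forms for -ed/-ing inflections."""
    out: list[str] = []
    if token.endswith("ied") and len(token) > 4:
        out.append(token[:-3] + "y")
    if token.endswith("ed") and len(token) > 3:
        stem = token[:-2]
        out.extend([stem, stem + "e"])
        undoubled = _undouble(stem)
        if undoubled:
            out.append(undoubled)
        out.append(token[:-1])  # "lounged" -> "lounge"
    if token.endswith("ing") and len(token) > 4:
        stem = token[:-3]
        out.extend([stem, stem + "e"])
        undoubled = _undouble(stem)
        if undoubled:
            out.append(undoubled)
    return _dedupe(out, token)


def adjective_candidates(token: str) -> list[str]:
    """Candidate base adjectives for comparative/superlative forms."""
    out: list[str] = []
    if token.endswith("iest") and len(token) > 5:
        out.append(token[:-4] + "y")
    if token.endswith("est") and len(token) > 4:
        stem = token[:-3]
        out.extend([stem, stem + "e"])
        undoubled = _undouble(stem)
        if undoubled:
            out.append(undoubled)
    if token.endswith("ier") and len(token) > 4:
        out.append(token[:-3] + "y")
    if token.endswith("er") and len(token) > 3:
        stem = token[:-2]
        out.extend([stem, stem + "e"])
        undoubled = _undouble(stem)
        if undoubled:
            out.append(undoubled)
    return _dedupe(out, token)


def _dedupe(candidates: list[str], original: str) -> list[str]:
    seen = {original}
    out = []
    for c in candidates:
        if c and c not in seen:
            seen.add(c)
            out.append(c)
    return out
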