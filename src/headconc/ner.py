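"""Named-entity detection for headlines.

Entities of interest are people, places, and organizations; every entity is
later scored at the concreteness ceiling of 5.  The default backend is a
deterministic rule/gazetteer tagger with no external model dependency, so the
pipeline is fully reproducible offline.  Additional backends can be
registered (e.g. a statistical tagger) and are selected by name; requesting a
backend that is not available raises :class:`BackendUnavailableError` rather
than silently returning zero entities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable

from .stopwords import ENGLISH_STOPWORDS

PERSON = "person"
PLACE = "place"
ORGANIZATION = "organization"


class BackendUnavailableError(RuntimeError):
    """Raised when the requested NER backend cannot be loaded."""


@dataclass(frozen=True)
class EntitySpan:
    """A non-overlapping character span labeled person/place/organization."""

    start: int
    end: int
    text: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in (PERSON, PLACE, ORGANIZATION):
            raise ValueError(f"unknown entity label: {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("invalid span bounds")


# Gazetteers are intentionally compact: they anchor the rule tagger on
# unambiguous single-token entities; multi-token capitalized runs are tagged
# by shape even when absent from the lists.
GIVEN_NAMES: frozenset[str] = frozenset("""
aaron abigail adam alan albert alexander alice amanda amy andrew angela ann
anna anthony arthur ashley barack barbara benjamin bernie beth betty beyonce
bill bob bonnie brandon brenda brian bruce carl carol carolyn catherine
charles charlotte cheryl chris christina christine christopher cynthia dan
daniel david deborah debra dennis diana diane donald donna dorothy douglas
dwayne edward elizabeth ellen emily emma eric eugene evelyn frances frank
fred gary george gerald gloria grace greg gregory hannah harold harris heather
helen henry hillary howard jack jacob james jane janet jason jean jeff
jeffrey jennifer jeremy jerry jesse jessica jill jim joan joe john johnny
jonathan jordan jose joseph joshua joyce juan judith judy julia julie justin
kamala karen katherine kathleen kathryn kathy keith kelly kenneth kevin kim
kimberly kyle larry laura lauren lawrence linda lisa logan lori louis
madison malala margaret maria marie marilyn mark martha martin mary matthew
megan melissa michael michelle mike nancy natalie nathan nicholas nicole
noah olivia oprah pamela patricia patrick paul peter philip rachel ralph
randy raymond rebecca richard robert roger ronald rose roy russell ruth ryan
samantha samuel sandra sara sarah scott sean sharon shirley sophia stephanie
stephen steve steven susan teresa terry theresa thomas timothy tyler victoria
vincent virginia walter wayne william willie zach zachary
""".split())

PLACE_NAMES: frozenset[str] = frozenset("""
afghanistan africa alabama alaska albania algeria america argentina arizona
arkansas asia atlanta australia austria baghdad baltimore bangladesh beijing
belgium berlin boston brazil britain brooklyn bulgaria cairo california
cambodia canada charlotte chicago chile china cincinnati cleveland colombia
colorado columbus connecticut cuba dallas delaware denmark denver detroit
dublin egypt england ethiopia europe finland florida france georgia germany
greece haiti hawaii holland hollywood houston idaho illinois india indiana
indianapolis indonesia iowa iran iraq ireland israel istanbul italy jamaica
japan jerusalem kabul kansas kentucky kenya korea kyiv lebanon libya london
louisiana madrid maine manhattan maryland massachusetts melbourne memphis
mexico miami michigan milwaukee minneapolis minnesota mississippi missouri
montana montreal morocco moscow mumbai nashville nebraska nepal netherlands
nevada nigeria norway ohio oklahoma oregon orleans pakistan palestine paris
pennsylvania peru philadelphia philippines phoenix pittsburgh poland
portland portugal rome russia rwanda sacramento scotland seattle seoul
serbia singapore somalia spain sudan sweden switzerland sydney syria
taiwan tennessee texas thailand tokyo toronto turkey uganda ukraine utah
venezuela vermont vietnam virginia wales washington wisconsin wyoming yemen
york zealand zimbabwe
""".split())

ORG_WORDS: frozenset[str] = frozenset("""
academy agency airlines army assembly association bank board bureau church
city college commission committee company congress corp corporation council
court department facebook fbi federation foundation google group hospital
house inc institute league microsoft ministry nasa nato navy network
organization parliament party police school senate society twitter un
union united university upworthy youtube
""".split())

_TOKEN_RE = re.compile(r"[A-Za-z][A-Za-z'’\-]*")


def _is_capitalized(tok: str) -> bool:
    return tok[0].isupper()


def _rule_detect(text: str) -> list[EntitySpan]:
    tokens = [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    spans: list[EntitySpan] = []
    run: list[tuple[str, int, int]] = []

    def flush() -> None:
        if not run:
            return
        words = [t[0] for t in run]
        lowers = [re.sub(r"['’]s$", "", w.lower()) for w in words]
        joined = " ".join(lowers)
        label = None
        if joined in PLACE_NAMES or any(w in PLACE_NAMES for w in lowers):
            label = PLACE
        elif any(w in ORG_WORDS for w in lowers):
            label = ORGANIZATION
        elif lowers[0] in GIVEN_NAMES:
            label = PERSON
        elif len(run) >= 2:
            # Multi-token capitalized run: name-shaped, default to person.
            label = PERSON
        if label is not None:
            spans.append(
                EntitySpan(run[0][1], run[-1][2], text[run[0][1] : run[-1][2]], label)
            )
        run.clear()

    for tok, start, end in tokens:
        low = tok.lower()
        qualifies = _is_capitalized(tok) and not (
            low in ENGLISH_STOPWORDS
            and low not in GIVEN_NAMES
            and low not in PLACE_NAMES
        )
        if qualifies:
            run.append((tok, start, end))
        else:
            flush()
    flush()
    return spans


_BACKENDS: dict[str, Callable[[str], list[EntitySpan]]] = {"rule": _rule_detect}


def register_backend(name: str, fn: Callable[[str], list[EntitySpan]]) -> None:
    _BACKENDS[name] = fn


def available_backends() -> Iterable[str]:
    return tuple(_BACKENDS)


def detect_entities(text: str, backend: str = "rule") -> list[EntitySpan]:
    """Return non-overlapping person/place/organization spans in ``text``.

    Runs on the original-cased text; capitalization is part of the signal.
    """
    if not text or not text.strip():
        raise ValueError("headline must be non-empty")
    fn = _BACKENDS.get(backend)
    if fn is None:
        raise BackendUnavailableError(
            f"NER backend {backend!r} is not available; registered: {sorted(_BACKENDS)}"
        )
    spans = sorted(fn(text), key=lambda s: s.start)
    for a, b in zip(spans, spans[1:]):
        if b.start < a.end:
            raise ValueError("backend produced overlapping entity spans")
    return spans
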