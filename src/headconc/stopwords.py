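"""English stopword list and the retained-word exceptions.

The stopword inventory mirrors the standard English list shipped with common
NLP toolkits.  Forward-reference words and personal pronouns are kept as
scoreable candidates because they do carry information-gap signal in
headlines; the retained set is overridable per call.
"""

from __future__ import annotations

ENGLISH_STOPWORDS: frozenset[str] = frozenset("""
i me my myself we our ours ourselves you you're you've you'll you'd your
yours yourself yourselves he him his himself she she's her hers herself it
it's its itself they them their theirs themselves what which who whom this
that that'll these those am is are was were be been being have has had
having do does did doing a an the and but if or because as until while of
at by for with about against between into through during before after
above below to from up down in out on off over under again further then
once here there when where why how all any both each few more most other
some such no nor not only own same so than too very s t can will just don
don't should should've now d ll m o re ve y ain aren aren't couldn
couldn't didn didn't doesn doesn't hadn hadn't hasn hasn't haven haven't
isn isn't ma mightn mightn't mustn mustn't needn needn't shan shan't
shouldn shouldn't wasn wasn't weren weren't won won't wouldn wouldn't
""".split())

#: Deictic forward references deliberately kept during filtering.
FORWARD_REFERENCES: frozenset[str] = frozenset({"this", "these", "that", "those"})

#: Personal pronouns deliberately kept during filtering.
PRONOUNS: frozenset[str] = frozenset(
    {"she", "he", "they", "her", "him", "them", "it", "we", "you", "i"}
)

DEFAULT_RETAINED: frozenset[str] = FORWARD_REFERENCES | PRONOUNS
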