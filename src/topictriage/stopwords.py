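"""Fixed English stop-word list, version 1.

Runs must be reproducible, so the package pins its own list instead of
depending on whatever list an NLP toolkit ships at import time.  The list
covers determiners, pronouns, auxiliaries, conjunctions, prepositions and
a handful of high-frequency adverbs — the usual closed-class English words.
Stop-word removal is applied to lowercased tokens before stemming.
"""

STOPWORDS_VERSION = "en-1"

STOPWORDS = frozenset(
    """
    a about above after again against all almost along already also although
    always am among amongst an and another any anyone anything are around as
    at be became because become becomes been before being below between both
    but by came can cannot could did do does doing done down during each
    either else enough etc even ever every everything few for found from
    further get gets give given gives had has have having he hence her here
    hers herself him himself his how however i if in into is it its itself
    just least less let like made make makes many may me meanwhile might
    more moreover most mostly much must my myself neither never nevertheless
    next no nor not nothing now of off often on once one only onto or other
    others otherwise our ours ourselves out over own per perhaps please quite
    rather really regarding same seem seemed seems several shall she should
    since so some somehow someone something sometimes somewhere still such
    than that the their theirs them themselves then there thereafter thereby
    therefore these they this those though through throughout thus to
    together too toward towards under unless until up upon us used using
    various very via was we well were what whatever when whenever where
    whereas whether which while who whom whose why will with within without
    would yet you your yours yourself yourselves
    """.split()
)
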