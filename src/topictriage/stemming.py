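"""English Snowball stemmer (Porter2).

A from-scratch implementation of the Porter2 algorithm: the standard English
stemmer used throughout biomedical text mining (it is what maps *studies* →
``studi``, *response* → ``respons``, *induced* → ``induc``).  The
implementation follows the published algorithm definition: R1/R2 regions,
steps 0–5, the exceptional word forms, and the consonant-``y`` marking.

Only :func:`stem` is public.  Tokens are expected lowercase; anything the
algorithm does not recognise passes through unchanged.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiouy")  # consonant y is re-marked as "Y" internally
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_ENDINGS = frozenset("cdeghkmnrt")

# full-word exceptional forms, applied before anything else
_EXCEPTIONAL = {
    "skis": "ski", "skies": "sky",
    "dying": "die", "lying": "lie", "tying": "tie",
    "idly": "idl", "gently": "gentl", "ugly": "ugli", "early": "earli",
    "only": "onli", "singly": "singl",
    # invariant forms
    "sky": "sky", "news": "news", "howe": "howe", "atlas": "atlas",
    "cosmos": "cosmos", "bias": "bias", "andes": "andes",
}

# words left untouched after step 1a
_STOP_AFTER_1A = frozenset(
    ["inning", "outing", "canning", "herring", "earring",
     "proceed", "exceed", "succeed"]
)

_STEP2 = (
    ("ization", "ize"), ("ational", "ate"), ("fulness", "ful"),
    ("ousness", "ous"), ("iveness", "ive"), ("tional", "tion"),
    ("biliti", "ble"), ("lessli", "less"), ("entli", "ent"),
    ("ation", "ate"), ("alism", "al"), ("aliti", "al"), ("ousli", "ous"),
    ("iviti", "ive"), ("fulli", "ful"), ("enci", "ence"), ("anci", "ance"),
    ("abli", "able"), ("izer", "ize"), ("ator", "ate"), ("alli", "al"),
    ("bli", "ble"), ("ogi", "og"), ("li", ""),
)

_STEP3 = (
    ("ational", "ate"), ("tional", "tion"), ("alize", "al"),
    ("icate", "ic"), ("iciti", "ic"), ("ative", ""), ("ical", "ic"),
    ("ness", ""), ("ful", ""),
)

_STEP4 = (
    "ement", "ance", "ence", "able", "ible", "ment",
    "ant", "ent", "ism", "ate", "iti", "ous", "ive", "ize", "ion",
    "al", "er", "ic",
)


def _is_vowel(ch: str) -> bool:
    return ch in _VOWELS


def _region_after(word: str, begin: int) -> int:
    """Position after the first vowel–non-vowel pair at or beyond *begin*."""
    for i in range(begin, len(word) - 1):
        if _is_vowel(word[i]) and not _is_vowel(word[i + 1]):
            return i + 2
    return len(word)


def _r1_start(word: str) -> int:
    for prefix in ("gener", "commun", "arsen"):
        if word.startswith(prefix):
            return len(prefix)
    return _region_after(word, 0)


def _ends_short_syllable(word: str) -> bool:
    n = len(word)
    if n == 2:
        return _is_vowel(word[0]) and not _is_vowel(word[1])
    if n >= 3:
        a, b, c = word[-3], word[-2], word[-1]
        return (
            _is_vowel(b)
            and not _is_vowel(c) and c not in "wxY"
            and not _is_vowel(a)
        )
    return False


def _is_short(word: str, r1: int) -> bool:
    return r1 >= len(word) and _ends_short_syllable(word)


def _mark_consonant_y(word: str) -> str:
    chars = list(word)
    if chars[0] == "y":
        chars[0] = "Y"
    for i in range(1, len(chars)):
        if chars[i] == "y" and _is_vowel(chars[i - 1]):
            chars[i] = "Y"
    return "".join(chars)


def stem(token: str) -> str:
    """Return the Porter2 stem of a lowercase token."""
    word = token
    if word.startswith("'"):
        word = word[1:]
    if len(word) <= 2:
        return word
    if word in _EXCEPTIONAL:
        return _EXCEPTIONAL[word]

    word = _mark_consonant_y(word)
    r1 = _r1_start(word)
    r2 = _region_after(word, r1)

    # step 0: apostrophe suffixes
    for suf in ("'s'", "'s", "'"):
        if word.endswith(suf):
            word = word[: -len(suf)]
            break

    # step 1a
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith(("ied", "ies")):
        word = word[:-2] if len(word) > 4 else word[:-1]
    elif word.endswith(("us", "ss")):
        pass
    elif word.endswith("s"):
        if any(_is_vowel(c) for c in word[:-2]):
            word = word[:-1]

    if word in _STOP_AFTER_1A:
        return word.replace("Y", "y")

    # step 1b
    suffix = next(
        (s for s in ("eedly", "ingly", "edly", "eed", "ing", "ed")
         if word.endswith(s)),
        None,
    )
    if suffix in ("eed", "eedly"):
        if len(word) - len(suffix) >= r1:
            word = word[: -len(suffix)] + "ee"
    elif suffix is not None:
        base = word[: -len(suffix)]
        if any(_is_vowel(c) for c in base):
            word = base
            if word.endswith(("at", "bl", "iz")):
                word += "e"
            elif word.endswith(_DOUBLES):
                word = word[:-1]
            elif _is_short(word, r1):
                word += "e"

    # step 1c: y -> i after a non-vowel that is not the first letter
    if len(word) > 2 and word[-1] in "yY" and not _is_vowel(word[-2]):
        word = word[:-1] + "i"

    # step 2 (longest suffix; act only if it lies in R1)
    for suf, rep in _STEP2:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "ogi":
                    if len(word) >= 4 and word[-4] == "l":
                        word = word[:-3] + "og"
                elif suf == "li":
                    if len(word) >= 3 and word[-3] in _LI_ENDINGS:
                        word = word[:-2]
                else:
                    word = word[: -len(suf)] + rep
            break

    # step 3 (in R1; "ative" requires R2)
    for suf, rep in _STEP3:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "ative":
                    if len(word) - len(suf) >= r2:
                        word = word[: -len(suf)]
                else:
                    word = word[: -len(suf)] + rep
            break

    # step 4 (in R2; "ion" only after s/t)
    for suf in _STEP4:
        if word.endswith(suf):
            if len(word) - len(suf) >= r2:
                if suf == "ion":
                    if len(word) >= 4 and word[-4] in "st":
                        word = word[:-3]
                else:
                    word = word[: -len(suf)]
            break

    # step 5
    if word.endswith("e"):
        if len(word) - 1 >= r2 or (
            len(word) - 1 >= r1 and not _ends_short_syllable(word[:-1])
        ):
            word = word[:-1]
    elif word.endswith("ll") and len(word) - 1 >= r2:
        word = word[:-1]

    return word.replace("Y", "y")
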