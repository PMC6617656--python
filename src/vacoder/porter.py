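"""Porter suffix-stripping stemmer.

Classic rule-based English stemmer: strips morphological endings so that
inflected forms share a stem (``crying`` -> ``cry``, ``injuries`` ->
``injuri``).  Implements the original 1980 algorithm (steps 1a-5b) without
later revisions.  Input is assumed lowercase; words of length <= 2 are
returned unchanged.
"""

from __future__ import annotations

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return True if i == 0 else not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel-consonant sequences (the m of [C](VC)^m[V])."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_cons(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant, final consonant not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace_if(word: str, suffix: str, repl: str, min_m: int) -> str | None:
    """Replace ``suffix`` by ``repl`` when the remaining stem has measure > min_m."""
    if word.endswith(suffix):
        stem = word[: len(word) - len(suffix)]
        if _measure(stem) > min_m:
            return stem + repl
        return word
    return None


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def stem_word(word: str) -> str:
    """Return the stem of a single lowercase word.

    Applies the Porter pass to a fixed point, which makes stemming a
    projection: ``stem_word(stem_word(w)) == stem_word(w)``.  (A single
    Porter pass is not idempotent — e.g. it maps ``houses`` to ``hous``
    and ``hous`` to ``hou`` — which would make repeated preprocessing
    unstable.)  Reference single-pass results such as ``crying -> cry``
    and ``injuries -> injuri`` are already fixed points and are unchanged.
    """
    out = _porter_pass(word)
    for _ in range(5):
        again = _porter_pass(out)
        if again == out:
            return out
        out = again
    return out


def _porter_pass(word: str) -> str:
    """One application of the Porter algorithm (steps 1a-5b)."""
    if len(word) <= 2:
        return word
    w = word

    # Step 1a — plurals
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    # Step 1b — -eed, -ed, -ing
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        stripped = None
        if w.endswith("ed") and _has_vowel(w[:-2]):
            stripped = w[:-2]
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            stripped = w[:-3]
        if stripped is not None:
            w = stripped
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # Step 1c — y -> i after a vowel-bearing stem
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2 — double suffixes (m > 0)
    for suffix, repl in _STEP2:
        out = _replace_if(w, suffix, repl, 0)
        if out is not None:
            w = out
            break

    # Step 3 — -ic-, -full, -ness etc. (m > 0)
    for suffix, repl in _STEP3:
        out = _replace_if(w, suffix, repl, 0)
        if out is not None:
            w = out
            break

    # Step 4 — bare suffixes (m > 1); -ion only after s or t
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if _measure(stem) > 1 and (suffix != "ion" or stem[-1:] in ("s", "t")):
                w = stem
            break

    # Step 5a — final e
    if w.endswith("e"):
        m = _measure(w[:-1])
        if m > 1 or (m == 1 and not _ends_cvc(w[:-1])):
            w = w[:-1]

    # Step 5b — -ll -> -l (m > 1)
    if _measure(w[:-1]) > 1 and _ends_double_cons(w) and w[-1] == "l":
        w = w[:-1]

    return w
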