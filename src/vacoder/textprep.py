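"""Narrative preprocessing: spelling correction, tokenization, stopwords, stemming.

VA narratives are transcribed (and often translated) by non-medical
surveyors, so they carry frequent spelling errors and grammatical
inconsistencies.  The pipeline applied to each narrative is:

1. :func:`normalize` — lowercase, detach punctuation, split on whitespace;
2. :func:`correct_spelling` — nearest-lexicon-entry correction (edit
   distance <= 2, distance 1 preferred, ties broken by corpus frequency
   then lexicographically);
3. :func:`remove_stopwords` — drop a fixed list of 160 function words;
4. :func:`stem` — Porter suffix stripping (``crying`` -> ``cry``).

Case is normalized before correction rather than after (lexicon lookup is
case-insensitive, so the output is unaffected).  Lexicon and stopword
resources are plain one-term-per-line text files and are replaceable.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

from .porter import stem_word

logger = logging.getLogger(__name__)

_PUNCT = set("!\"#$%&'()*+,-./:;<=>?@[\\]^_`{|}~")


def _load_resource(name: str) -> list[str]:
    text = (
        importlib_resources.files("vacoder").joinpath("resources", name).read_text()
    )
    return [line.strip().lower() for line in text.splitlines() if line.strip()]


@dataclass
class Lexicon:
    """Case-insensitive word list used as the spelling-correction target.

    ``base`` is general English; ``custom`` holds domain terms that must
    never themselves be "corrected".  ``frequencies`` (optional) supplies
    corpus counts used to break ties between correction candidates.
    """

    base: frozenset[str]
    custom: frozenset[str] = frozenset()
    frequencies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.base = frozenset(w.lower() for w in self.base)
        self.custom = frozenset(w.lower() for w in self.custom)
        self._all = self.base | self.custom
        self._sorted = sorted(self._all)

    def __contains__(self, token: str) -> bool:
        return token.lower() in self._all

    def __len__(self) -> int:
        return len(self._all)

    def words(self) -> list[str]:
        return list(self._sorted)

    def update_frequencies(self, tokens: Iterable[str]) -> None:
        for t in tokens:
            t = t.lower()
            if t in self._all:
                self.frequencies[t] = self.frequencies.get(t, 0) + 1

    @classmethod
    def default(cls, extra_terms: Iterable[str] = ()) -> "Lexicon":
        """English base list + shipped hand-crafted medical term list."""
        return cls(
            base=frozenset(_load_resource("english_lexicon.txt")),
            custom=frozenset(_load_resource("medical_lexicon.txt"))
            | frozenset(w.lower() for w in extra_terms),
        )

    @classmethod
    def from_files(
        cls, base_path: str | Path, custom_path: str | Path | None = None
    ) -> "Lexicon":
        base = frozenset(
            w.strip().lower() for w in Path(base_path).read_text().splitlines() if w.strip()
        )
        custom: frozenset[str] = frozenset()
        if custom_path is not None:
            custom = frozenset(
                w.strip().lower()
                for w in Path(custom_path).read_text().splitlines()
                if w.strip()
            )
        return cls(base=base, custom=custom)


class StopwordList:
    """Ordered set of lowercase stopwords (default resource has 160 entries)."""

    def __init__(self, words: Sequence[str]):
        seen: list[str] = []
        for w in words:
            w = w.strip().lower()
            if w and w not in seen:
                seen.append(w)
        self._words = tuple(seen)
        self._set = frozenset(seen)
        logger.info("stopword list loaded: %d entries", len(self._words))

    def __contains__(self, token: str) -> bool:
        return token.lower() in self._set

    def __len__(self) -> int:
        return len(self._words)

    def __iter__(self):
        return iter(self._words)

    @classmethod
    def default(cls) -> "StopwordList":
        return cls(_load_resource("stopwords_160.txt"))

    @classmethod
    def from_file(cls, path: str | Path) -> "StopwordList":
        return cls(Path(path).read_text().splitlines())


@dataclass
class Correction:
    """One logged spelling substitution (or a flagged uncorrectable token)."""

    original: str
    corrected: str
    distance: int


@dataclass
class TokenizedNarrative:
    """A record's fully preprocessed narrative: ordered word stems."""

    record_id: str
    tokens: list[str]
    flagged_empty: bool = False


def normalize(text: str) -> list[str]:
    """Lowercase and split text into word and punctuation tokens.

    Punctuation characters are detached as their own tokens.  Tokens that
    contain digits (dates like ``13/03/01``) are kept whole apart from
    leading/trailing punctuation.
    """
    out: list[str] = []
    for chunk in text.lower().split():
        if any(ch.isdigit() for ch in chunk):
            start, end = 0, len(chunk)
            while start < end and chunk[start] in _PUNCT:
                out.append(chunk[start])
                start += 1
            trail: list[str] = []
            while end > start and chunk[end - 1] in _PUNCT:
                trail.append(chunk[end - 1])
                end -= 1
            if end > start:
                out.append(chunk[start:end])
            out.extend(reversed(trail))
        else:
            run = ""
            for ch in chunk:
                if ch in _PUNCT:
                    if run:
                        out.append(run)
                        run = ""
                    out.append(ch)
                else:
                    run += ch
            if run:
                out.append(run)
    return out


def _is_correctable(token: str) -> bool:
    return token.isalpha() and len(token) >= 2


def _distance_cap(token: str, max_distance: int) -> int:
    # short tokens admit too many spurious candidates at distance 2
    return 1 if len(token) <= 4 else max_distance


def _osa_distance(a: str, b: str, cap: int) -> int:
    """Optimal-string-alignment (Damerau) distance, capped at ``cap`` + 1.

    Counts an adjacent transposition as a single edit — the dominant class
    of typing errors — unlike plain Levenshtein which charges it two.
    """
    la, lb = len(a), len(b)
    if abs(la - lb) > cap:
        return cap + 1
    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                prev2 is not None
                and i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        if min(cur) > cap:
            return cap + 1
        prev2, prev = prev, cur
    return min(prev[lb], cap + 1)


def _best_candidate(
    token: str, lexicon: Lexicon, max_distance: int
) -> tuple[str, int] | None:
    """Nearest lexicon entry: smallest OSA distance, then highest corpus
    frequency, then lexicographic order.

    A fast banded Levenshtein (edlib) pass prefilters candidates: a
    transposition costs 2 Levenshtein edits, so OSA <= d implies
    Levenshtein <= 2d.
    """
    best: tuple[int, int, str] | None = None
    for word in lexicon.words():
        if abs(len(word) - len(token)) > max_distance:
            continue
        lev = edlib.align(token, word, task="distance", k=2 * max_distance)[
            "editDistance"
        ]
        if lev < 0:
            continue
        d = lev if lev <= 1 else _osa_distance(token, word, max_distance)
        if d > max_distance:
            continue
        key = (d, -lexicon.frequencies.get(word, 0), word)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], best[0]


def correct_spelling(
    tokens: Sequence[str],
    lexicon: Lexicon,
    max_distance: int = 2,
    log: list[Correction] | None = None,
    _cache: dict[str, str] | None = None,
) -> list[str]:
    """Replace out-of-lexicon alphabetic tokens by their nearest lexicon entry.

    Punctuation, digit-bearing tokens, single characters and in-lexicon
    tokens pass through unchanged; tokens of up to 4 characters are only
    corrected to distance-1 candidates.  A token with no candidate within
    the distance bound also passes through (flagged in the log with
    distance -1).  Substitutions are appended to ``log`` when given.
    """
    cache = _cache if _cache is not None else {}
    out: list[str] = []
    for token in tokens:
        if not _is_correctable(token) or token in lexicon:
            out.append(token)
            continue
        if token in cache:
            fixed = cache[token]
            if log is not None and fixed != token:
                log.append(Correction(token, fixed, -2))  # cached; distance not recomputed
            out.append(fixed)
            continue
        found = _best_candidate(token, lexicon, _distance_cap(token, max_distance))
        if found is None:
            cache[token] = token
            if log is not None:
                log.append(Correction(token, token, -1))
            logger.debug("no correction within distance %d: %r", max_distance, token)
            out.append(token)
        else:
            word, d = found
            cache[token] = word
            if log is not None:
                log.append(Correction(token, word, d))
            out.append(word)
    return out


def remove_stopwords(
    tokens: Sequence[str], stopwords: StopwordList
) -> list[str]:
    """Order-preserving stopword filter."""
    kept = [t for t in tokens if t not in stopwords]
    logger.debug("stopword filter removed %d of %d tokens", len(tokens) - len(kept), len(tokens))
    return kept


def stem(tokens: Sequence[str]) -> list[str]:
    """Porter-stem alphabetic tokens; others pass through unchanged."""
    return [stem_word(t) if t.isalpha() else t for t in tokens]


def resources_hash(lexicon: Lexicon, stopwords: StopwordList) -> str:
    """Stable digest of the preprocessing resources, for provenance logging."""
    h = hashlib.sha256()
    for w in lexicon.words():
        h.update(w.encode())
        h.update(b"\0")
    h.update(b"\1")
    for w in stopwords:
        h.update(w.encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def preprocess(
    text: str,
    lexicon: Lexicon,
    stopwords: StopwordList,
    record_id: str = "",
    correction_log: list[Correction] | None = None,
    _cache: dict[str, str] | None = None,
) -> TokenizedNarrative:
    """Full pipeline for one narrative; deterministic for fixed resources.

    Punctuation-only tokens are dropped at the end (they carry no lexical
    content for a bag-of-words model).  A narrative that reduces to nothing
    is flagged.
    """
    tokens = normalize(text)
    tokens = correct_spelling(tokens, lexicon, log=correction_log, _cache=_cache)
    tokens = remove_stopwords(tokens, stopwords)
    tokens = stem(tokens)
    tokens = [t for t in tokens if not all(ch in _PUNCT for ch in t)]
    flagged = not tokens
    if flagged:
        warnings.warn(f"record {record_id!r}: narrative empty after preprocessing")
    return TokenizedNarrative(record_id=record_id, tokens=tokens, flagged_empty=flagged)


def preprocess_corpus(
    records,
    lexicon: Lexicon | None = None,
    stopwords: StopwordList | None = None,
    correction_log: list[Correction] | None = None,
) -> list[TokenizedNarrative]:
    """Preprocess a corpus of VA records.

    In-lexicon token frequencies are tallied across the corpus first so
    that spelling-correction ties favour words actually used in these
    narratives.  The resource hash is logged for provenance.
    """
    lexicon = lexicon or Lexicon.default()
    stopwords = stopwords or StopwordList.default()
    logger.info("preprocessing resources hash: %s", resources_hash(lexicon, stopwords))
    for r in records:
        lexicon.update_frequencies(normalize(r.narrative))
    cache: dict[str, str] = {}
    return [
        preprocess(
            r.narrative,
            lexicon,
            stopwords,
            record_id=r.record_id,
            correction_log=correction_log,
            _cache=cache,
        )
        for r in records
    ]
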