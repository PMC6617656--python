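"""Seeded generator of synthetic VA corpora.

The real study corpora (physician-coded VA narratives from India and South
Africa) are not publicly available, so this module generates stand-in
corpora with the same structural features: short noisy English narratives
built from cause-specific symptom vocabulary mixed with background
vocabulary, misspellings injected at a configurable per-token rate, three
age strata, and skewed cause-of-death distributions.

Narratives are assembled from category-independent templates, so the gold
label can leak into the text only through the symptom lexicon — which is
exactly the signal a bag-of-words classifier is supposed to recover.
"""

from __future__ import annotations

import copy
import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import CoDScheme, VARecord, default_scheme

#: Skewed default CSMF for the 15-category adult/child schemes (largest ~ 0.3).
SKEWED_CSMF_15 = (
    0.30, 0.14, 0.10, 0.08, 0.07, 0.06, 0.05, 0.04,
    0.035, 0.03, 0.025, 0.02, 0.02, 0.015, 0.015,
)
#: Skewed default CSMF for the 5-category neonatal scheme.
SKEWED_CSMF_5 = (0.35, 0.25, 0.20, 0.12, 0.08)

# Default class-conditional symptom vocabularies.  Deliberately overlapping
# across related causes, as in real narratives.
DEFAULT_CATEGORY_LEXICONS: dict[str, tuple[str, ...]] = {
    "Acute respiratory infections": (
        "cough", "fever", "chest", "breathless", "pneumonia", "sputum",
        "cold", "wheezing",
    ),
    "Diarrhea": (
        "loose", "stool", "vomiting", "dehydration", "watery", "motions",
        "stomach", "weakness",
    ),
    "Pulmonary tuberculosis": (
        "tuberculosis", "cough", "blood", "sputum", "weight", "night",
        "sweats", "thin",
    ),
    "Other and unspecified infections": (
        "fever", "chills", "infection", "typhoid", "malaria", "rash",
        "headache", "sepsis",
    ),
    "Neoplasms": (
        "cancer", "tumor", "lump", "growth", "swelling", "weight",
        "pain", "spreading",
    ),
    "Nutrition": (
        "weakness", "anemia", "thin", "appetite", "pale", "emaciated",
        "malnutrition", "weight",
    ),
    "Cardiovascular disease": (
        "heart", "chest", "pain", "attack", "pressure", "palpitation",
        "sweating", "collapsed",
    ),
    "Chronic respiratory disease": (
        "asthma", "breathless", "wheezing", "smoking", "chronic", "cough",
        "oxygen", "chest",
    ),
    "Liver cirrhosis": (
        "liver", "jaundice", "yellow", "ascites", "alcohol", "abdomen",
        "swelling", "vomiting",
    ),
    "Other non-communicable diseases": (
        "diabetes", "sugar", "kidney", "urine", "stroke", "paralysis",
        "unconscious", "pressure",
    ),
    "Road and transport injuries": (
        "road", "accident", "vehicle", "truck", "motorcycle", "head",
        "injury", "bleeding",
    ),
    "Other injuries": (
        "fall", "fracture", "burn", "snake", "bite", "poison",
        "drowning", "wound",
    ),
    "Ill-defined": (
        "weakness", "aged", "sudden", "unknown", "tired", "dull",
        "fever", "pain",
    ),
    "Suicide": (
        "hanging", "poison", "pesticide", "consumed", "suicide", "rope",
        "depressed", "quarrel",
    ),
    "Maternal": (
        "delivery", "pregnancy", "pregnant", "bleeding", "labour",
        "childbirth", "placenta", "anemia",
    ),
    "Prematurity/low birth weight": (
        "premature", "small", "weight", "birth", "weak", "incubator",
        "tiny", "month",
    ),
    "Neonatal infections": (
        "fever", "infection", "sepsis", "umbilical", "refused", "suck",
        "lethargic", "rash",
    ),
    "Birth asphyxia/trauma": (
        "asphyxia", "cry", "delivery", "prolonged", "blue", "breathe",
        "obstructed", "trauma",
    ),
    "Ill-defined or cause unknown": (
        "sudden", "unknown", "normal", "sleeping", "stopped", "cause",
        "night", "quiet",
    ),
    "Other": (
        "jaundice", "yellow", "congenital", "defect", "heart",
        "malformation", "vomiting", "diarrhea",
    ),
}

DEFAULT_BACKGROUND_LEXICON: tuple[str, ...] = (
    "village", "hospital", "doctor", "medicine", "treatment", "home",
    "family", "morning", "evening", "condition", "worse", "local",
    "private", "admitted", "referred", "returned", "gradually",
    "complained", "history", "eating", "drinking", "walking", "working",
    "neighbour", "relatives", "clinic", "checkup", "advised", "visited",
)

# Category-independent narrative templates; {S} is replaced by the sampled
# symptom/background token sequence and {D} by a small number.
_TEMPLATES: tuple[str, ...] = (
    "the deceased was suffering from {S} for {D} days and passed away at home .",
    "the patient had {S} and was taken to the hospital where the patient died .",
    "the subject complained of {S} since {D} months and the condition became worse .",
    "the person developed {S} and despite treatment at the local clinic the person expired .",
    "the deceased suffered {S} and died on the way to the hospital .",
)


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic corpus; sufficient to regenerate it.

    ``background_weight`` is the mixture weight lambda: each content token
    comes from the background lexicon with probability lambda and from the
    record's category lexicon otherwise.  ``misspelling_rate`` rho corrupts
    each alphabetic token independently by one random edit.
    """

    scheme: CoDScheme = field(default_factory=default_scheme)
    csmf_by_age_group: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "adult": SKEWED_CSMF_15,
            "child": SKEWED_CSMF_15,
            "neonate": SKEWED_CSMF_5,
        }
    )
    n_per_age_group: dict[str, int] = field(
        default_factory=lambda: {"adult": 1000, "child": 200, "neonate": 100}
    )
    category_lexicons: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_LEXICONS)
    )
    background_lexicon: tuple[str, ...] = DEFAULT_BACKGROUND_LEXICON
    background_weight: float = 0.3
    length_min: int = 4
    length_mean: float = 9.0
    length_max: int = 25
    misspelling_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.background_weight <= 1.0:
            raise ValueError("background_weight must be in [0,1]")
        if not 0.0 <= self.misspelling_rate < 1.0:
            raise ValueError("misspelling_rate must be in [0,1)")
        for group, csmf in self.csmf_by_age_group.items():
            cats = self.scheme.categories(group)
            if len(csmf) != len(cats):
                raise ValueError(
                    f"{group}: CSMF length {len(csmf)} != {len(cats)} categories"
                )
            if abs(sum(csmf) - 1.0) > 1e-9 or min(csmf) < 0:
                raise ValueError(f"{group}: CSMF must be a probability vector")
            if self.background_weight < 1.0:
                for c in cats:
                    if not self.category_lexicons.get(c):
                        raise ValueError(f"empty symptom lexicon for category {c!r}")

    def all_vocabulary(self) -> list[str]:
        """Every word the generator can emit (for building a correction lexicon)."""
        words = set(self.background_lexicon)
        for lex in self.category_lexicons.values():
            words.update(lex)
        for t in _TEMPLATES:
            words.update(w for w in t.replace("{S}", "").replace("{D}", "").split() if w.isalpha())
        return sorted(words)


@dataclass
class Misspelling:
    """One logged corruption: which token of which record, and both forms."""

    record_id: str
    position: int
    original: str
    corrupted: str


@dataclass
class SyntheticCorpus:
    """Generated records + the manifest needed to regenerate them bit-identically."""

    records: list[VARecord]
    config: GeneratorConfig
    realized_csmf: dict[str, tuple[float, ...]]
    misspellings: list[Misspelling]

    @property
    def manifest(self) -> dict:
        return {
            "seed": self.config.seed,
            "n_per_age_group": dict(self.config.n_per_age_group),
            "background_weight": self.config.background_weight,
            "misspelling_rate": self.config.misspelling_rate,
            "realized_csmf": {g: list(v) for g, v in self.realized_csmf.items()},
            "n_misspellings": len(self.misspellings),
        }


_ALPHABET = string.ascii_lowercase


def _one_random_edit(word: str, rng: np.random.Generator) -> str:
    """Apply one random substitution/deletion/insertion/transposition."""
    for _ in range(20):
        op = rng.integers(0, 4)
        chars = list(word)
        if op == 0 and len(chars) >= 1:  # substitute
            i = int(rng.integers(0, len(chars)))
            chars[i] = _ALPHABET[int(rng.integers(0, 26))]
        elif op == 1 and len(chars) >= 2:  # delete
            i = int(rng.integers(0, len(chars)))
            del chars[i]
        elif op == 2:  # insert
            i = int(rng.integers(0, len(chars) + 1))
            chars.insert(i, _ALPHABET[int(rng.integers(0, 26))])
        elif op == 3 and len(chars) >= 2:  # transpose
            i = int(rng.integers(0, len(chars) - 1))
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
        out = "".join(chars)
        if out != word:
            return out
    return word + _ALPHABET[int(rng.integers(0, 26))]


def inject_misspellings(
    tokens: Sequence[str], rate: float, rng: np.random.Generator
) -> tuple[list[str], list[tuple[int, str, str]]]:
    """Corrupt each alphabetic token independently with probability ``rate``.

    Returns the noisy tokens and a log of (position, original, corrupted).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0,1)")
    out: list[str] = []
    log: list[tuple[int, str, str]] = []
    for i, tok in enumerate(tokens):
        if tok.isalpha() and rate > 0 and rng.random() < rate:
            bad = _one_random_edit(tok, rng)
            log.append((i, tok, bad))
            out.append(bad)
        else:
            out.append(tok)
    return out, log


def _make_narrative(
    category: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    record_id: str,
    log: list[Misspelling],
) -> str:
    lam = config.background_weight
    cat_lex = config.category_lexicons.get(category, ())
    n_content = int(
        np.clip(rng.poisson(config.length_mean), config.length_min, config.length_max)
    )
    content: list[str] = []
    for _ in range(n_content):
        if (lam > 0 and rng.random() < lam) or not cat_lex:
            content.append(str(rng.choice(config.background_lexicon)))
        else:
            content.append(str(rng.choice(cat_lex)))
    template = _TEMPLATES[int(rng.integers(0, len(_TEMPLATES)))]
    days = str(int(rng.integers(1, 30)))
    tokens = []
    for word in template.split():
        if word == "{S}":
            tokens.extend(content)
        elif word == "{D}":
            tokens.append(days)
        else:
            tokens.append(word)
    noisy, edit_log = inject_misspellings(tokens, config.misspelling_rate, rng)
    for pos, orig, bad in edit_log:
        log.append(Misspelling(record_id, pos, orig, bad))
    return " ".join(noisy)


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Draw a full synthetic corpus; byte-identical for identical config + seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[VARecord] = []
    realized: dict[str, tuple[float, ...]] = {}
    log: list[Misspelling] = []
    for group in sorted(config.n_per_age_group):
        n = config.n_per_age_group[group]
        cats = config.scheme.categories(group)
        probs = np.asarray(config.csmf_by_age_group[group], dtype=float)
        draws = rng.choice(len(cats), size=n, p=probs)
        counts = np.bincount(draws, minlength=len(cats))
        realized[group] = tuple(counts / max(n, 1))
        for i, ci in enumerate(draws):
            rid = f"synth-{group}-{i:05d}"
            narrative = _make_narrative(cats[ci], config, rng, rid, log)
            records.append(
                VARecord(
                    record_id=rid,
                    age_group=group,
                    narrative=narrative,
                    category=cats[ci],
                    source_tag="synthetic",
                )
            )
    return SyntheticCorpus(
        records=records, config=config, realized_csmf=realized, misspellings=log
    )


_CONSONANTS = "bdfgklmnprtvz"
_VOWELS = "aiou"


def disjoint_lexicons(
    categories: Sequence[str],
    words_per_category: int = 8,
    seed: int = 0,
) -> dict[str, tuple[str, ...]]:
    """Pairwise-disjoint pseudo-word symptom lexicons, one per category.

    Words are pronounceable consonant-vowel strings whose Porter stems are
    also pairwise distinct (features are stems, so stem collisions would
    break disjointness downstream).
    """
    from .porter import stem_word

    rng = np.random.default_rng(seed)
    used_words: set[str] = set()
    used_stems: set[str] = set()
    out: dict[str, tuple[str, ...]] = {}
    for cat in categories:
        words: list[str] = []
        while len(words) < words_per_category:
            n_syll = int(rng.integers(3, 5))
            w = "".join(
                _CONSONANTS[int(rng.integers(0, len(_CONSONANTS)))]
                + _VOWELS[int(rng.integers(0, len(_VOWELS)))]
                for _ in range(n_syll)
            )
            s = stem_word(w)
            if w in used_words or s in used_stems:
                continue
            used_words.add(w)
            used_stems.add(s)
            words.append(w)
        out[cat] = tuple(words)
    return out


def signal_sweep(
    base_config: GeneratorConfig,
    signal_levels: Sequence[float],
    families: Sequence[str] = ("naive_bayes",),
    k_folds: int = 10,
    seed: int = 0,
) -> list[dict]:
    """Re-run the cross-validated experiment at several background weights.

    Returns one row per lambda level with the per-family weighted
    sensitivity and CCCSMFA (averaged over age groups); sensitivity is
    non-increasing in lambda in expectation.
    """
    from .crossval import run_experiment  # local import avoids a cycle
    from .textprep import Lexicon

    rows = []
    for lam in signal_levels:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("signal levels must be in [0,1]")
        config = copy.deepcopy(base_config)
        config.background_weight = lam
        corpus = generate_corpus(config)
        # the generator vocabulary doubles as the custom correction lexicon
        lexicon = Lexicon.default(extra_terms=config.all_vocabulary())
        report = run_experiment(
            corpus.records,
            config.scheme,
            families=families,
            k=k_folds,
            seed=seed,
            lexicon=lexicon,
            chance_iterations=2000,
        )
        for family in families:
            sens = np.mean(
                [
                    report.mean(group, family, "sensitivity")
                    for group in report.age_groups
                ]
            )
            ccc = np.mean(
                [
                    report.mean(group, family, "cccsmfa")
                    for group in report.age_groups
                ]
            )
            rows.append(
                {
                    "lambda": lam,
                    "family": family,
                    "sensitivity": float(sens),
                    "cccsmfa": float(ccc),
                }
            )
    return rows
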