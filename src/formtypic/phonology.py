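"""Phoneme inventory handling and word-form encoding.

A :class:`PhonemeInventory` maps segment symbols to articulatory feature
bundles (place/manner/voicing for consonants; place/height/rounding for
vowels) and assigns each symbol a numeric id by configuration order.
:func:`encode_word` turns a transcribed word into a named vector of form
variables: whole-word feature counts, initial/final-position feature
indicators, segment counts, initial/final phoneme ids and the lexical
stress position category. The default roster has 83 variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .filters import AffectRatings

__all__ = [
    "CONSONANT_PLACES",
    "MANNERS",
    "VOICINGS",
    "VOWEL_PLACES",
    "HEIGHTS",
    "ROUNDINGS",
    "Phoneme",
    "PhonemeInventory",
    "WordEntry",
    "load_inventory",
    "form_variable_names",
    "encode_word",
    "encode_lexicon",
    "parse_transcription",
    "format_transcription",
]

CONSONANT_PLACES = ("bilabial", "labiodental", "dental", "alveolar",
                    "palatal", "velar", "labiovelar")
MANNERS = ("plosive", "nasal", "fricative", "affricate", "lateral",
           "trill", "tap", "approximant")
VOICINGS = ("voiced", "voiceless")
VOWEL_PLACES = ("front", "central", "back")
HEIGHTS = ("open", "mid", "close")
ROUNDINGS = ("rounded", "unrounded")

#: (group key, category values) in roster order.
_FEATURE_GROUPS = (
    ("cplace", CONSONANT_PLACES),
    ("manner", MANNERS),
    ("voicing", VOICINGS),
    ("vplace", VOWEL_PLACES),
    ("height", HEIGHTS),
    ("rounding", ROUNDINGS),
)


@dataclass(frozen=True)
class Phoneme:
    """One inventory segment with its articulatory feature bundle."""

    symbol: str
    klass: str  # 'vowel' | 'consonant'
    place: str
    numeric_id: int
    manner: Optional[str] = None
    voicing: Optional[str] = None
    height: Optional[str] = None
    rounding: Optional[str] = None

    @property
    def is_vowel(self) -> bool:
        return self.klass == "vowel"


class PhonemeInventory:
    """Validated ordered collection of :class:`Phoneme` entries.

    Numeric ids equal the 1-based position in the configured order, so
    id-valued predictors are only comparable within one configuration.
    """

    def __init__(self, entries: Sequence[Phoneme], inventory_id: str = "custom"):
        if not entries:
            raise ValueError("empty phoneme inventory")
        seen: set[str] = set()
        for ph in entries:
            if ph.symbol in seen:
                raise ValueError(f"duplicate phoneme symbol {ph.symbol!r}")
            seen.add(ph.symbol)
            self._validate(ph)
        self.entries: tuple[Phoneme, ...] = tuple(entries)
        self.inventory_id = inventory_id
        self._by_symbol = {ph.symbol: ph for ph in entries}

    @staticmethod
    def _validate(ph: Phoneme) -> None:
        if ph.klass == "consonant":
            if ph.place not in CONSONANT_PLACES:
                raise ValueError(f"{ph.symbol!r}: bad consonant place {ph.place!r}")
            if ph.manner not in MANNERS:
                raise ValueError(f"{ph.symbol!r}: bad or missing manner {ph.manner!r}")
            if ph.voicing not in VOICINGS:
                raise ValueError(f"{ph.symbol!r}: bad or missing voicing {ph.voicing!r}")
            if ph.height is not None or ph.rounding is not None:
                raise ValueError(f"{ph.symbol!r}: consonant carries vowel features")
        elif ph.klass == "vowel":
            if ph.place not in VOWEL_PLACES:
                raise ValueError(f"{ph.symbol!r}: bad vowel place {ph.place!r}")
            if ph.height not in HEIGHTS:
                raise ValueError(f"{ph.symbol!r}: bad or missing height {ph.height!r}")
            if ph.rounding not in ROUNDINGS:
                raise ValueError(f"{ph.symbol!r}: bad or missing rounding {ph.rounding!r}")
            if ph.manner is not None:
                raise ValueError(f"{ph.symbol!r}: vowel carries a manner feature")
            if ph.voicing not in (None, "voiced"):
                raise ValueError(f"{ph.symbol!r}: vowels must be voiced")
        else:
            raise ValueError(f"{ph.symbol!r}: unknown class {ph.klass!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __getitem__(self, symbol: str) -> Phoneme:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise KeyError(f"phoneme {symbol!r} not in inventory "
                           f"{self.inventory_id!r}") from None

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(ph.symbol for ph in self.entries)

    def vowels(self) -> tuple[Phoneme, ...]:
        return tuple(ph for ph in self.entries if ph.is_vowel)

    def consonants(self) -> tuple[Phoneme, ...]:
        return tuple(ph for ph in self.entries if not ph.is_vowel)


def load_inventory(config_path=None) -> PhonemeInventory:
    """Load a phoneme inventory from YAML, or the packaged Castilian
    default (31 segments) when ``config_path`` is None.

    The YAML maps ``phonemes`` to a list of feature bundles; numeric ids
    are assigned by listing order, starting at 1.
    """
    if config_path is None:
        text = resources.files("formtypic.data").joinpath(
            "es_castilian_31.yaml").read_text("utf-8")
    else:
        with open(config_path, encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not doc or "phonemes" not in doc or not doc["phonemes"]:
        raise ValueError("inventory config is empty or lacks a 'phonemes' list")
    entries = []
    for i, row in enumerate(doc["phonemes"], start=1):
        entries.append(Phoneme(
            symbol=str(row["symbol"]),
            klass=row["class"],
            place=row["place"],
            numeric_id=i,
            manner=row.get("manner"),
            voicing=row.get("voicing", "voiced" if row["class"] == "vowel" else None),
            height=row.get("height"),
            rounding=row.get("rounding"),
        ))
    return PhonemeInventory(entries, inventory_id=str(doc.get("id", "custom")))


@dataclass
class WordEntry:
    """One lexicon row: orthography, transcription, stress, POS, ratings.

    ``syllable_breaks`` are the 0-based start indices of syllables 2..k in
    the phoneme list (e.g. ``b a . l a`` -> phonemes ``[b,a,l,a]``, breaks
    ``[2]``); ``stress_syllable`` is 1-based.
    """

    word: str
    phonemes: list[str]
    syllable_breaks: list[int]
    stress_syllable: int
    pos: str
    ratings: Optional[AffectRatings] = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.phonemes:
            raise ValueError(f"{self.word!r}: empty phoneme list")
        prev = 0
        for b in self.syllable_breaks:
            if not (0 < b < len(self.phonemes)) or b <= prev:
                raise ValueError(f"{self.word!r}: bad syllable breaks "
                                 f"{self.syllable_breaks}")
            prev = b
        if not (1 <= self.stress_syllable <= self.n_syllables):
            raise ValueError(f"{self.word!r}: stress syllable "
                             f"{self.stress_syllable} out of range "
                             f"1..{self.n_syllables}")

    @property
    def n_syllables(self) -> int:
        return len(self.syllable_breaks) + 1

    @property
    def transcription(self) -> str:
        return format_transcription(self.phonemes, self.syllable_breaks)


def parse_transcription(text: str) -> tuple[list[str], list[int]]:
    """Parse a space-separated transcription with ``.`` syllable breaks
    into ``(phonemes, syllable_breaks)``."""
    phonemes: list[str] = []
    breaks: list[int] = []
    last_was_break = True  # leading '.' is malformed
    for tok in text.split():
        if tok == ".":
            if last_was_break:
                raise ValueError(f"malformed transcription {text!r}")
            breaks.append(len(phonemes))
            last_was_break = True
        else:
            phonemes.append(tok)
            last_was_break = False
    if last_was_break and phonemes:
        raise ValueError(f"malformed transcription {text!r} (trailing '.')")
    if not phonemes:
        raise ValueError(f"empty transcription {text!r}")
    return phonemes, breaks


def format_transcription(phonemes: Sequence[str], breaks: Sequence[int]) -> str:
    toks: list[str] = []
    bset = set(breaks)
    for i, ph in enumerate(phonemes):
        if i in bset:
            toks.append(".")
        toks.append(ph)
    return " ".join(toks)


def form_variable_names(*, voicing_includes_vowels: bool = False) -> list[str]:
    """Stable roster of form-variable names (83 by default).

    Layout: 3 length measures, 2 phoneme-id predictors, then for each of
    the whole-word (``n_``), initial (``init_``) and final (``final_``)
    scopes the 25 feature categories, then 3 stress-position indicators.
    """
    names = ["length_letters", "n_phonemes", "n_syllables",
             "initial_phoneme_id", "final_phoneme_id"]
    for scope in ("n", "init", "final"):
        for group, cats in _FEATURE_GROUPS:
            names.extend(f"{scope}_{group}_{c}" for c in cats)
    names += ["stress_initial", "stress_medial", "stress_final"]
    return names


def _feature_keys(ph: Phoneme, voicing_includes_vowels: bool) -> list[str]:
    """Category keys (group_value) active for one phoneme."""
    if ph.is_vowel:
        keys = [f"vplace_{ph.place}", f"height_{ph.height}",
                f"rounding_{ph.rounding}"]
        if voicing_includes_vowels:
            keys.append("voicing_voiced")
        return keys
    return [f"cplace_{ph.place}", f"manner_{ph.manner}",
            f"voicing_{ph.voicing}"]


def _stress_category(stress_syllable: int, n_syllables: int) -> str:
    # Monosyllables are final-stressed by convention so the three
    # categories partition all words.
    if n_syllables == 1:
        return "final"
    if stress_syllable == n_syllables:
        return "final"
    if stress_syllable == 1:
        return "initial"
    return "medial"


def encode_word(entry: WordEntry, inv: PhonemeInventory,
                *, voicing_includes_vowels: bool = False) -> dict[str, float]:
    """Encode one word into the named form-variable vector.

    Deterministic and pure; raises ``KeyError`` for phonemes not in the
    inventory. Voicing counts cover consonants only unless
    ``voicing_includes_vowels`` is set (vowels are uniformly voiced and
    would otherwise duplicate the vowel count).
    """
    names = form_variable_names(voicing_includes_vowels=voicing_includes_vowels)
    vec = dict.fromkeys(names, 0.0)
    segs = [inv[s] for s in entry.phonemes]

    vec["length_letters"] = float(len(entry.word))
    vec["n_phonemes"] = float(len(segs))
    vec["n_syllables"] = float(entry.n_syllables)
    vec["initial_phoneme_id"] = float(segs[0].numeric_id)
    vec["final_phoneme_id"] = float(segs[-1].numeric_id)

    for ph in segs:
        for key in _feature_keys(ph, voicing_includes_vowels):
            vec[f"n_{key}"] += 1.0
    for key in _feature_keys(segs[0], voicing_includes_vowels):
        vec[f"init_{key}"] = 1.0
    for key in _feature_keys(segs[-1], voicing_includes_vowels):
        vec[f"final_{key}"] = 1.0

    vec[f"stress_{_stress_category(entry.stress_syllable, entry.n_syllables)}"] = 1.0
    return vec


def encode_lexicon(entries: Iterable[WordEntry], inv: PhonemeInventory,
                   *, voicing_includes_vowels: bool = False
                   ) -> tuple[np.ndarray, list[str]]:
    """Encode a lexicon into an ``n x p`` matrix plus column names.

    Validates every entry before emitting output so a failure produces no
    partial matrix. Column order is identical across calls with the same
    configuration.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("empty entry list")
    names = form_variable_names(voicing_includes_vowels=voicing_includes_vowels)
    rows = [encode_word(e, inv, voicing_includes_vowels=voicing_includes_vowels)
            for e in entries]
    X = np.array([[row[c] for c in names] for row in rows], dtype=float)
    return X, names
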