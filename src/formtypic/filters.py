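"""Word-inclusion pipeline: rating-agreement cutoff, part-of-speech
exclusion, orthographic prefix stripping, and the emotionality transform.

All filter operations partition their input into ``(kept, removed)`` and are
pure: entries are never mutated. The canonical pipeline order is
agreement -> POS -> prefix, wrapped by :func:`run_filters`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "AffectRatings",
    "FilterReport",
    "DEFAULT_EXCLUDED_POS",
    "agreement_filter",
    "pos_filter",
    "strip_prefixed",
    "derive_emotionality",
    "load_prefixes",
    "run_filters",
]

#: POS labels excluded by default (numbers, proper names, adpositions,
#: dates, determiners, interjections, pronouns).
DEFAULT_EXCLUDED_POS = frozenset(
    {"number", "proper_name", "adposition", "date", "determiner",
     "interjection", "pronoun"}
)

_KNOWN_POS = frozenset({"noun", "adjective", "verb", "adverb"}) | DEFAULT_EXCLUDED_POS

_SCALE_MIN, _SCALE_MID, _SCALE_MAX = 1.0, 5.0, 9.0


def derive_emotionality(valence_mean: float) -> float:
    """Absolute distance of a valence mean from the scale midpoint (5).

    Parameters
    ----------
    valence_mean : float
        Mean valence rating on the 1-9 scale.

    Returns
    -------
    float
        Emotionality on [0, 4]; 0 for neutral words, 4 at either extreme.
    """
    if not (_SCALE_MIN <= valence_mean <= _SCALE_MAX):
        raise ValueError(
            f"valence mean {valence_mean!r} outside the [1, 9] rating scale"
        )
    return abs(valence_mean - _SCALE_MID)


@dataclass(frozen=True)
class AffectRatings:
    """Per-word affective rating summary on nine-point scales."""

    valence_mean: float
    valence_sd: float
    arousal_mean: float
    arousal_sd: float

    def __post_init__(self) -> None:
        for name in ("valence_mean", "arousal_mean"):
            v = getattr(self, name)
            if not (_SCALE_MIN <= v <= _SCALE_MAX):
                raise ValueError(f"{name}={v!r} outside the [1, 9] rating scale")
        for name in ("valence_sd", "arousal_sd"):
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"{name} is missing")
            if v < 0:
                raise ValueError(f"{name}={v!r} is negative")

    @property
    def emotionality(self) -> float:
        """Derived emotionality, ``|valence_mean - 5|`` on [0, 4]."""
        return derive_emotionality(self.valence_mean)


@dataclass
class FilterReport:
    """Row-count bookkeeping for one pass through the filter pipeline."""

    n_input: int = 0
    n_after_agreement: int = 0
    n_after_pos: int = 0
    n_after_prefix: int = 0
    removed: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_agreement": self.n_after_agreement,
            "n_after_pos": self.n_after_pos,
            "n_after_prefix": self.n_after_prefix,
            "removed": [list(pair) for pair in self.removed],
        }


def _ratings_of(entry) -> AffectRatings:
    r = getattr(entry, "ratings", None)
    if r is None:
        raise ValueError(f"entry {getattr(entry, 'word', entry)!r} has no ratings")
    return r


def agreement_filter(entries: Iterable, cutoff: float = 1.5):
    """Keep entries whose valence AND arousal rating SDs are strictly below
    ``cutoff`` (default 1.5); drop the rest as poor-agreement words."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    kept, removed = [], []
    for entry in entries:
        r = _ratings_of(entry)
        if r.valence_sd is None or r.arousal_sd is None:
            raise ValueError(f"entry {entry.word!r} is missing a rating SD")
        if r.valence_sd < 0 or r.arousal_sd < 0:
            raise ValueError(f"entry {entry.word!r} has a negative rating SD")
        if r.valence_sd < cutoff and r.arousal_sd < cutoff:
            kept.append(entry)
        else:
            removed.append(entry)
    return kept, removed


def pos_filter(entries: Iterable, excluded=DEFAULT_EXCLUDED_POS, *, strict: bool = False):
    """Drop entries whose POS label is in ``excluded``.

    Unknown POS labels (not in the excluded set and not one of the four
    content-word classes) are kept with a warning, or raise when
    ``strict=True``.
    """
    excluded = frozenset(excluded)
    kept, removed = [], []
    for entry in entries:
        pos = entry.pos
        if pos is None:
            raise ValueError(f"entry {entry.word!r} has no POS label")
        if pos in excluded:
            removed.append(entry)
            continue
        if pos not in _KNOWN_POS and not pos.startswith("other:"):
            if strict:
                raise ValueError(f"unknown POS label {pos!r} for {entry.word!r}")
            warnings.warn(f"unknown POS label {pos!r} for {entry.word!r}; kept",
                          stacklevel=2)
        kept.append(entry)
    return kept, removed


def load_prefixes(path=None) -> list[str]:
    """Load a prefix list (one per line, ``#`` comments) or the packaged
    default Spanish list."""
    if path is None:
        text = resources.files("formtypic.data").joinpath("prefixes_es.txt").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.lower())
    return out


def strip_prefixed(entries: Iterable, prefixes: Sequence[str]):
    """Remove entries whose orthographic word starts with any listed prefix.

    Matching is case-insensitive; the removal reason records the longest
    matching prefix. Returns ``(kept, removed_with_reasons)`` where the
    second element is a list of ``(entry, matched_prefix)``.
    """
    prefixes = list(prefixes)
    if not prefixes:
        raise ValueError("prefix list is empty")
    for p in prefixes:
        if not isinstance(p, str) or p == "":
            raise ValueError(f"invalid prefix {p!r}")
    by_len = sorted((p.lower() for p in prefixes), key=len, reverse=True)
    kept, removed = [], []
    for entry in entries:
        w = entry.word.lower()
        match = next((p for p in by_len if w.startswith(p)), None)
        if match is None:
            kept.append(entry)
        else:
            removed.append((entry, match))
    return kept, removed


def run_filters(entries: Sequence, cutoff: float = 1.5,
                excluded=DEFAULT_EXCLUDED_POS,
                prefixes: Sequence[str] | None = None,
                *, strict_pos: bool = False):
    """Apply agreement -> POS -> prefix filtering and return
    ``(kept_entries, FilterReport)``."""
    entries = list(entries)
    report = FilterReport(n_input=len(entries))

    kept, rm = agreement_filter(entries, cutoff)
    report.removed += [(e.word, "rating_disagreement") for e in rm]
    report.n_after_agreement = len(kept)

    kept, rm = pos_filter(kept, excluded, strict=strict_pos)
    report.removed += [(e.word, f"pos:{e.pos}") for e in rm]
    report.n_after_pos = len(kept)

    if prefixes is None:
        prefixes = load_prefixes()
    kept, rm = strip_prefixed(kept, prefixes)
    report.removed += [(e.word, f"prefix:{p}") for e, p in rm]
    report.n_after_prefix = len(kept)
    return kept, report
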