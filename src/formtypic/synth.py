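"""Synthetic Spanish-like lexicons with a multi-rater affect model.

Words are built from sampled (C)V(C) syllables over the active phoneme
inventory; affect ratings come from a latent-mean model with planted
linear form-variable effects at a configurable population R-squared, and
per-word integer rater samples on the nine-point scale (including a
disagreement subpopulation drawn from a separated two-component mixture).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .filters import AffectRatings
from .phonology import PhonemeInventory, WordEntry, encode_lexicon, load_inventory

__all__ = [
    "GeneratorConfig",
    "generate_lexicon",
    "plant_affect",
    "plant_covariates",
    "plant_item_data",
    "make_fixture",
    "FIXTURE_WORDS",
]

# phoneme -> orthography for synthetic words
_ORTHO = {
    "a": "a", "e": "e", "i": "i", "o": "o", "u": "u",
    "p": "p", "b": "b", "t": "t", "d": "d", "k": "c", "g": "g",
    "tʃ": "ch", "f": "f", "θ": "z", "s": "s", "z": "s", "ʝ": "y",
    "x": "j", "m": "m", "n": "n", "ɲ": "ñ", "ŋ": "n", "l": "l",
    "ʎ": "ll", "r": "rr", "ɾ": "r", "j": "i", "w": "u",
    "β": "b", "ð": "d", "ɣ": "g",
}

_DEFAULT_ONSETS = ["p", "b", "t", "d", "k", "g", "f", "s", "m", "n",
                   "l", "r", "ɾ", "tʃ", "x", "θ", "ʝ", "ɲ", "ʎ", "w", "j"]
_DEFAULT_NUCLEI = ["a", "e", "i", "o", "u"]
_DEFAULT_NUCLEUS_P = [0.28, 0.26, 0.14, 0.22, 0.10]
_DEFAULT_CODAS = ["n", "s", "ɾ", "l", "d", "θ"]

# prefix -> syllable phoneme lists, used to exercise prefix stripping
_PREFIX_PHONEMES = {
    "in": [["i", "n"]],
    "des": [["d", "e", "s"]],
    "re": [["ɾ", "e"]],
    "pre": [["p", "ɾ", "e"]],
    "sub": [["s", "u", "b"]],
    "anti": [["a", "n"], ["t", "i"]],
}


@dataclass
class Phonotactics:
    onsets: list[str] = field(default_factory=lambda: list(_DEFAULT_ONSETS))
    onset_probs: Optional[list[float]] = None
    nuclei: list[str] = field(default_factory=lambda: list(_DEFAULT_NUCLEI))
    nucleus_probs: Optional[list[float]] = field(
        default_factory=lambda: list(_DEFAULT_NUCLEUS_P))
    codas: list[str] = field(default_factory=lambda: list(_DEFAULT_CODAS))
    coda_probs: Optional[list[float]] = None
    p_onset: float = 0.9
    p_coda: float = 0.35


@dataclass
class GeneratorConfig:
    n_words: int = 500
    seed: int = 0
    syllable_range: tuple[int, int] = (1, 4)
    phonotactics: Phonotactics = field(default_factory=Phonotactics)
    pos_probs: dict[str, float] = field(default_factory=lambda: {
        "noun": 0.62, "adjective": 0.16, "verb": 0.19, "adverb": 0.03})
    prefix_rate: float = 0.0
    raters_per_word: int = 30
    rater_sd: float = 1.0
    disagreement_rate: float = 0.0
    disagreement_separation: float = 4.0
    planted_beta: dict[str, dict[str, float]] = field(default_factory=dict)
    target_r2: dict[str, float] = field(default_factory=dict)
    latent_sd: float = 1.2
    affect_corr: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.syllable_range
        if not (1 <= lo <= hi <= 8):
            raise ValueError("syllable_range must lie within [1, 8]")
        tot = sum(self.pos_probs.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError("pos_probs must sum to 1")
        if not (0.0 <= self.prefix_rate <= 1.0):
            raise ValueError("prefix_rate must be in [0, 1]")
        if not (0.0 <= self.disagreement_rate <= 1.0):
            raise ValueError("disagreement_rate must be in [0, 1]")
        if self.rater_sd < 0:
            raise ValueError("rater_sd must be >= 0")
        if self.raters_per_word < 2:
            raise ValueError("raters_per_word must be >= 2")


def _pick(rng, items, probs):
    if probs is None:
        return items[rng.integers(len(items))]
    return items[rng.choice(len(items), p=np.asarray(probs) / np.sum(probs))]


def generate_lexicon(config: GeneratorConfig,
                     inventory: Optional[PhonemeInventory] = None
                     ) -> list[WordEntry]:
    """Sample ``n_words`` phonotactically plausible word entries (without
    ratings); deterministic under ``config.seed``."""
    inventory = inventory or load_inventory()
    pt = config.phonotactics
    if not pt.onsets or not pt.nuclei:
        raise ValueError("empty phoneme pools in phonotactics")
    for pool in (pt.onsets, pt.nuclei, pt.codas):
        for s in pool:
            if s not in inventory:
                raise ValueError(f"phonotactics symbol {s!r} not in inventory")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.syllable_range
    pos_labels = list(config.pos_probs)
    pos_p = np.array([config.pos_probs[k] for k in pos_labels], dtype=float)
    prefixes = list(_PREFIX_PHONEMES)

    entries: list[WordEntry] = []
    for _ in range(config.n_words):
        n_syll = int(rng.integers(lo, hi + 1))
        syllables: list[list[str]] = []
        for _s in range(n_syll):
            syl: list[str] = []
            if rng.random() < pt.p_onset:
                syl.append(_pick(rng, pt.onsets, pt.onset_probs))
            syl.append(_pick(rng, pt.nuclei, pt.nucleus_probs))
            if pt.codas and rng.random() < pt.p_coda:
                syl.append(_pick(rng, pt.codas, pt.coda_probs))
            syllables.append(syl)

        prefix_ortho = ""
        covariates = {}
        if config.prefix_rate > 0 and rng.random() < config.prefix_rate:
            pref = prefixes[rng.integers(len(prefixes))]
            syllables = [list(s) for s in _PREFIX_PHONEMES[pref]] + syllables
            prefix_ortho = pref
            covariates["planted_prefix"] = 1.0

        phonemes: list[str] = []
        breaks: list[int] = []
        for i, syl in enumerate(syllables):
            if i > 0:
                breaks.append(len(phonemes))
            phonemes.extend(syl)
        base_start = len(_PREFIX_PHONEMES[prefix_ortho]) if prefix_ortho else 0
        base_ortho = "".join(_ORTHO[s] for syl in syllables[base_start:]
                             for s in syl)
        word = prefix_ortho + base_ortho
        stress = int(rng.integers(1, len(syllables) + 1))
        pos = pos_labels[int(rng.choice(len(pos_labels), p=pos_p))]
        entries.append(WordEntry(word=word, phonemes=phonemes,
                                 syllable_breaks=breaks,
                                 stress_syllable=stress, pos=pos,
                                 covariates=covariates))
    return entries


def _planted_signal(X: np.ndarray, names: Sequence[str],
                    beta: dict[str, float]) -> np.ndarray:
    pos = {nm: j for j, nm in enumerate(names)}
    s = np.zeros(X.shape[0])
    for nm, b in beta.items():
        if nm not in pos:
            raise KeyError(f"planted variable {nm!r} is not a form variable")
        s += b * X[:, pos[nm]]
    return s - s.mean()


def _sample_raters(rng, mu: float, cfg: GeneratorConfig,
                   disagree: bool) -> np.ndarray:
    m = cfg.raters_per_word
    if disagree:
        side = rng.random(m) < 0.5
        centers = np.where(side, mu - cfg.disagreement_separation / 2.0,
                           mu + cfg.disagreement_separation / 2.0)
    else:
        centers = np.full(m, mu)
    draws = centers + rng.normal(0.0, cfg.rater_sd, m) if cfg.rater_sd > 0 \
        else centers.copy()
    return np.clip(np.rint(np.clip(draws, 1.0, 9.0)), 1, 9).astype(int)


def plant_affect(entries: Sequence[WordEntry], config: GeneratorConfig,
                 inventory: Optional[PhonemeInventory] = None
                 ) -> list[WordEntry]:
    """Attach affect ratings with planted form effects.

    The latent word mean for each dimension is the scale midpoint plus the
    centred planted signal plus Gaussian residual noise scaled so the
    population variance share of the signal equals ``target_r2``. Stored
    means/SDs are recomputed from the integer rater samples.
    """
    inventory = inventory or load_inventory()
    entries = list(entries)
    X, names = encode_lexicon(entries, inventory)
    rng = np.random.default_rng(config.seed + 1)
    n = len(entries)

    latents: dict[str, np.ndarray] = {}
    # correlated residuals across the two rated dimensions
    z = rng.multivariate_normal(
        [0.0, 0.0],
        [[1.0, config.affect_corr], [config.affect_corr, 1.0]], size=n)
    for d, dim in enumerate(("valence", "arousal")):
        beta = config.planted_beta.get(dim, {})
        r2 = float(config.target_r2.get(dim, 0.0))
        s = _planted_signal(X, names, beta)
        var_s = float(s.var())
        if r2 > 0 and var_s == 0.0:
            raise ValueError(
                f"target_r2>0 for {dim!r} but planted signal has zero variance")
        if r2 > 0:
            resid_sd = math.sqrt(var_s * (1.0 - r2) / r2)
        else:
            s = np.zeros(n)
            resid_sd = config.latent_sd
        latents[dim] = 5.0 + s + resid_sd * z[:, d]

    disagree = rng.random(n) < config.disagreement_rate
    out: list[WordEntry] = []
    for i, entry in enumerate(entries):
        samples = {dim: _sample_raters(rng, float(latents[dim][i]), config,
                                       bool(disagree[i]))
                   for dim in ("valence", "arousal")}
        ratings = AffectRatings(
            valence_mean=float(samples["valence"].mean()),
            valence_sd=float(samples["valence"].std(ddof=1)),
            arousal_mean=float(samples["arousal"].mean()),
            arousal_sd=float(samples["arousal"].std(ddof=1)),
        )
        e = replace(entry, ratings=ratings)
        e.raters = {k: v.copy() for k, v in samples.items()}
        out.append(e)
    return out


_COVARIATE_NAMES = ["length", "old", "bigram_freq", "phon_neighbours",
                    "zipf", "prevalence", "concreteness", "familiarity", "aoa"]


def plant_covariates(entries: Sequence[WordEntry], seed: int = 0
                     ) -> list[WordEntry]:
    """Attach plausible lexico-semantic covariates (length-linked where it
    matters, otherwise independent noise)."""
    rng = np.random.default_rng(seed + 2)
    out = []
    for entry in entries:
        L = len(entry.word)
        cov = dict(entry.covariates)
        cov["length"] = float(L)
        cov["old"] = float(max(1.0, 0.9 + 0.15 * L + rng.normal(0, 0.3)))
        cov["bigram_freq"] = float(max(100.0, rng.normal(5700, 3000)))
        cov["phon_neighbours"] = float(max(0.0, rng.normal(12 - L, 4)))
        cov["zipf"] = float(np.clip(rng.normal(3.7, 0.8), 1.0, 7.0))
        cov["prevalence"] = float(np.clip(rng.normal(2.3, 0.3), 0.5, 3.0))
        cov["concreteness"] = float(np.clip(rng.normal(4.6, 1.1), 1.0, 7.0))
        cov["familiarity"] = float(np.clip(rng.normal(5.1, 1.0), 1.0, 7.0))
        cov["aoa"] = float(np.clip(rng.normal(7.3, 2.0), 1.0, 15.0))
        out.append(replace(entry, covariates=cov))
    return out


def plant_item_data(entries: Sequence[WordEntry], seed: int = 0,
                    rt_noise_sd: float = 40.0) -> list[WordEntry]:
    """Attach item-level response data (mean RT in ms, error rate) driven
    by frequency, length and mild affect effects."""
    rng = np.random.default_rng(seed + 3)
    out = []
    for entry in entries:
        cov = dict(entry.covariates)
        if "zipf" not in cov:
            raise ValueError("plant_covariates must run before plant_item_data")
        r = entry.ratings
        affect = 0.0
        if r is not None:
            affect = -4.0 * (r.valence_mean - 5.0) + 2.0 * (r.arousal_mean - 5.0)
        rt = (700.0 - 35.0 * cov["zipf"] + 6.0 * cov["length"]
              + 5.0 * cov["aoa"] + affect + rng.normal(0.0, rt_noise_sd))
        err = (0.22 - 0.04 * cov["zipf"] + 0.01 * cov["aoa"]
               + rng.normal(0.0, 0.03))
        cov["rt"] = float(rt)
        cov["error_rate"] = float(np.clip(err, 0.0, 1.0))
        out.append(replace(entry, covariates=cov))
    return out


# ---------------------------------------------------------------------------
# packaged mini-fixture (hand-checkable transcriptions, incl. real words)

#: word, transcription, stress syllable, POS, valence mean/sd, arousal mean/sd
FIXTURE_WORDS: list[tuple] = [
    ("general",       "x e . n e . ɾ a l",          3, "adjective", 5.8, 1.1, 4.6, 1.2),
    ("panel",         "p a . n e l",                 2, "noun",      5.1, 0.9, 4.2, 1.0),
    ("huir",          "u . i ɾ",                     2, "verb",      3.2, 1.3, 6.4, 1.2),
    ("canal",         "k a . n a l",                 2, "noun",      5.4, 0.8, 4.4, 1.1),
    ("colateral",     "k o . l a . t e . ɾ a l",     4, "adjective", 4.6, 1.0, 4.8, 1.2),
    ("craneal",       "k ɾ a . n e . a l",           3, "adjective", 4.9, 1.1, 4.5, 1.3),
    ("peral",         "p e . ɾ a l",                 2, "noun",      5.9, 0.9, 3.6, 1.0),
    ("coronel",       "k o . ɾ o . n e l",           3, "noun",      5.0, 1.2, 4.9, 1.2),
    ("poligonal",     "p o . l i . g o . n a l",     4, "adjective", 5.0, 0.8, 4.1, 1.0),
    ("elemental",     "e . l e . m e n . t a l",     4, "adjective", 5.6, 0.9, 4.0, 1.1),
    ("unilateral",    "u . n i . l a . t e . ɾ a l", 5, "adjective", 4.5, 1.1, 4.6, 1.2),
    ("tifus",         "t i . f u s",                 1, "noun",      2.4, 1.2, 6.2, 1.3),
    ("hepatitis",     "e . p a . t i . t i s",       3, "noun",      2.2, 1.1, 6.3, 1.3),
    ("faringitis",    "f a . ɾ i n . x i . t i s",   3, "noun",      2.5, 1.0, 5.9, 1.2),
    ("meningitis",    "m e . n i n . x i . t i s",   3, "noun",      1.8, 1.0, 6.8, 1.2),
    ("conjuntivitis", "k o n . x u n . t i . b i . t i s", 4, "noun", 2.6, 1.1, 5.8, 1.3),
    ("apendicitis",   "a . p e n . d i . θ i . t i s", 4, "noun",    2.3, 1.1, 6.5, 1.2),
    ("cruel",         "k ɾ u e l",                   1, "adjective", 2.0, 1.2, 6.6, 1.3),
    ("local",         "l o . k a l",                 2, "adjective", 5.3, 0.8, 4.3, 1.0),
    ("laurel",        "l a u . ɾ e l",               2, "noun",      6.0, 0.9, 3.8, 1.0),
    ("mesa",          "m e . s a",                   1, "noun",      5.5, 0.7, 3.5, 0.9),
    ("perro",         "p e . r o",                   1, "noun",      6.8, 1.2, 5.2, 1.3),
    ("año",           "a . ɲ o",                     1, "noun",      5.9, 0.9, 4.4, 1.1),
    ("calle",         "k a . ʎ e",                   1, "noun",      5.2, 0.8, 4.7, 1.1),
    ("chico",         "tʃ i . k o",                  1, "noun",      6.1, 0.9, 4.8, 1.1),
    ("guerra",        "g e . r a",                   1, "noun",      1.5, 0.9, 7.8, 1.1),
    ("zorro",         "θ o . r o",                   1, "noun",      5.7, 1.0, 4.9, 1.2),
    ("huevo",         "w e . β o",                   1, "noun",      6.2, 0.8, 3.9, 1.0),
    ("yegua",         "ʝ e . g w a",                 1, "noun",      5.8, 0.9, 4.3, 1.1),
    ("jamón",         "x a . m o n",                 2, "noun",      7.0, 1.0, 4.6, 1.2),
    ("fatal",         "f a . t a l",                 2, "adverb",    1.9, 1.1, 6.9, 1.2),
]


def make_fixture(path=None) -> list[WordEntry]:
    """Build the ~30-word hand-transcribed mini-lexicon; optionally write
    it as a lexicon CSV at ``path``. All words pass the agreement filter
    by construction."""
    from .io import write_lexicon  # local import to avoid a cycle

    entries = []
    for word, trans, stress, pos, vm, vs, am, asd in FIXTURE_WORDS:
        from .phonology import parse_transcription
        phonemes, breaks = parse_transcription(trans)
        entries.append(WordEntry(
            word=word, phonemes=phonemes, syllable_breaks=breaks,
            stress_syllable=stress, pos=pos,
            ratings=AffectRatings(valence_mean=vm, valence_sd=vs,
                                  arousal_mean=am, arousal_sd=asd)))
    if path is not None:
        write_lexicon(entries, path)
    return entries
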