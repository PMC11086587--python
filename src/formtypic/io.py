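"""Lexicon readers/writers, the run manifest, and the study-level drivers.

CSV dialect: UTF-8, comma-separated, '.' decimal; the transcription column
is whitespace-separated phoneme symbols with '.' syllable separators and a
separate 1-based integer stress column.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .filters import AffectRatings, DEFAULT_EXCLUDED_POS, FilterReport, run_filters
from .model import (TypicalityConfig, TypicalityRun, run_typicality)
from .phonology import (PhonemeInventory, WordEntry, load_inventory,
                        parse_transcription)
from .stats import (bartlett_test, games_howell, hierarchical_regression,
                    spearman_matrix, welch_anova)

__all__ = [
    "REQUIRED_COLUMNS",
    "RunManifest",
    "read_lexicon",
    "write_lexicon",
    "Study1Config",
    "Study2Config",
    "Study3Config",
    "run_study1",
    "run_study2",
    "run_study3",
]

REQUIRED_COLUMNS = ("word", "transcription", "stress_syllable", "pos",
                    "valence_mean", "valence_sd", "arousal_mean", "arousal_sd")


@dataclass
class RunManifest:
    """Provenance record attached to every driver run."""

    config_hash: str
    seed: int
    inventory_id: str
    variable_roster: list[str]
    stage_rows: dict[str, int]
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2),
                              encoding="utf-8")


def _config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# lexicon CSV

def read_lexicon(path, inventory: Optional[PhonemeInventory] = None
                 ) -> list[WordEntry]:
    """Read a lexicon CSV into validated :class:`WordEntry` rows.

    Any numeric column beyond the required eight becomes a covariate.
    Per-row problems are aggregated into a single error listing row
    numbers (2-based, matching spreadsheet line numbers).
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lexicon {path} is missing required column(s): "
                         + ", ".join(missing))
    covariate_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]

    entries: list[WordEntry] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        try:
            phonemes, breaks = parse_transcription(str(row["transcription"]))
            ratings = AffectRatings(
                valence_mean=float(row["valence_mean"]),
                valence_sd=float(row["valence_sd"]),
                arousal_mean=float(row["arousal_mean"]),
                arousal_sd=float(row["arousal_sd"]))
            cov = {}
            for c in covariate_cols:
                v = row[c]
                if pd.notna(v) and not isinstance(v, str):
                    cov[c] = float(v)
            entry = WordEntry(word=str(row["word"]), phonemes=phonemes,
                              syllable_breaks=breaks,
                              stress_syllable=int(row["stress_syllable"]),
                              pos=str(row["pos"]), ratings=ratings,
                              covariates=cov)
            if inventory is not None:
                for s in phonemes:
                    if s not in inventory:
                        raise ValueError(f"phoneme {s!r} not in inventory")
            entries.append(entry)
        except (ValueError, KeyError) as exc:
            errors.append(f"row {rowno} ({row.get('word', '?')}): {exc}")
    if errors:
        raise ValueError(f"{len(errors)} invalid lexicon row(s):\n  "
                         + "\n  ".join(errors))
    return entries


def write_lexicon(entries: Sequence[WordEntry], path) -> None:
    """Write entries to a lexicon CSV (round-trips with read_lexicon)."""
    cov_names: list[str] = []
    for e in entries:
        for c in e.covariates:
            if c not in cov_names:
                cov_names.append(c)
    rows = []
    for e in entries:
        r = e.ratings
        row = {
            "word": e.word,
            "transcription": e.transcription,
            "stress_syllable": e.stress_syllable,
            "pos": e.pos,
            "valence_mean": r.valence_mean if r else np.nan,
            "valence_sd": r.valence_sd if r else np.nan,
            "arousal_mean": r.arousal_mean if r else np.nan,
            "arousal_sd": r.arousal_sd if r else np.nan,
        }
        for c in cov_names:
            row[c] = e.covariates.get(c, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def _entries_frame(entries: Sequence[WordEntry],
                   runs: dict[str, TypicalityRun]) -> pd.DataFrame:
    """Merge per-word ratings, covariates and typicality scores."""
    data = {
        "word": [e.word for e in entries],
        "pos": [e.pos for e in entries],
        "valence": [e.ratings.valence_mean for e in entries],
        "emotionality": [e.ratings.emotionality for e in entries],
        "arousal": [e.ratings.arousal_mean for e in entries],
    }
    cov_names = sorted({c for e in entries for c in e.covariates})
    for c in cov_names:
        data[c] = [e.covariates.get(c, np.nan) for e in entries]
    for dv, run in runs.items():
        data[f"typ_{dv}"] = run.scores.z
        data[f"typ_{dv}_fitted"] = run.scores.fitted
    return pd.DataFrame(data)


def _model_table(run: TypicalityRun) -> pd.DataFrame:
    return pd.DataFrame(run.model.table())


def _typicality_listing(df: pd.DataFrame, dv: str, k: int = 10) -> pd.DataFrame:
    """Top/bottom-k listing by z-scored typicality, with both scales."""
    s = df.sort_values(f"typ_{dv}", ascending=False)
    top = s.head(k)[["word", f"typ_{dv}", f"typ_{dv}_fitted"]]
    bot = s.tail(k)[["word", f"typ_{dv}", f"typ_{dv}_fitted"]]
    top = top.assign(group="most_typical")
    bot = bot.assign(group="least_typical")
    return pd.concat([top, bot], ignore_index=True)


DVS = ("valence", "emotionality", "arousal")


# ---------------------------------------------------------------------------
# study drivers

@dataclass
class Study1Config:
    seed: int = 0
    folds: int = 10
    repeats: int = 200
    kmax: int = 40
    hc_flavor: str = "HC2"
    agreement_cutoff: float = 1.5
    excluded_pos: frozenset = DEFAULT_EXCLUDED_POS
    prefixes: Optional[list[str]] = None
    exact_limit: int = 15
    outdir: Optional[str] = None


@dataclass
class Study1Result:
    kept: list[WordEntry]
    filter_report: FilterReport
    runs: dict[str, TypicalityRun]
    anova: dict[str, dict]
    listings: dict[str, pd.DataFrame]
    frame: pd.DataFrame
    manifest: RunManifest


def run_study1(entries: Sequence[WordEntry],
               inventory: Optional[PhonemeInventory] = None,
               config: Study1Config | None = None) -> Study1Result:
    """Filter the lexicon, fit the three typicality models, and compare
    typicality across POS (Bartlett, Welch ANOVA, Games-Howell)."""
    config = config or Study1Config()
    inventory = inventory or load_inventory()
    kept, report = run_filters(entries, cutoff=config.agreement_cutoff,
                               excluded=config.excluded_pos,
                               prefixes=config.prefixes)
    tc = TypicalityConfig(folds=config.folds, repeats=config.repeats,
                          seed=config.seed, kmax=config.kmax,
                          hc_flavor=config.hc_flavor,
                          exact_limit=config.exact_limit)
    runs = {dv: run_typicality(kept, inventory, dv, tc) for dv in DVS}
    frame = _entries_frame(kept, runs)

    groups = frame["pos"].to_numpy()
    counts = frame["pos"].value_counts()
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError("POS group(s) with fewer than 2 members: "
                         + ", ".join(map(str, small)))
    anova: dict[str, dict] = {}
    for dv in DVS:
        z = frame[f"typ_{dv}"].to_numpy()
        try:
            chi, df_b, p_b = bartlett_test(z, groups)
            wa = welch_anova(z, groups)
            gh = games_howell(z, groups)
        except ValueError as exc:
            # e.g. a POS group with constant scores under a degenerate
            # (single-indicator) model; keep the other DVs usable
            anova[dv] = {"error": str(exc)}
            continue
        anova[dv] = {
            "bartlett": {"chi_sq": chi, "df": df_b, "p": p_b},
            "welch": wa.__dict__,
            "games_howell": [r.__dict__ for r in gh],
        }
    listings = {dv: _typicality_listing(frame, dv) for dv in DVS}

    manifest = RunManifest(
        config_hash=_config_hash(config.__dict__ | {"study": 1}),
        seed=config.seed, inventory_id=inventory.inventory_id,
        variable_roster=list(runs["valence"].screen.kept_columns),
        stage_rows={"input": report.n_input,
                    "after_agreement": report.n_after_agreement,
                    "after_pos": report.n_after_pos,
                    "after_prefix": report.n_after_prefix})

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "filter_report.json").write_text(
            json.dumps(report.to_dict(), indent=2), encoding="utf-8")
        for dv in DVS:
            _model_table(runs[dv]).to_csv(out / f"model_{dv}.csv", index=False)
            frame[["word", "pos", f"typ_{dv}", f"typ_{dv}_fitted"]].to_csv(
                out / f"scores_{dv}.csv", index=False)
            listings[dv].to_csv(out / f"listing_{dv}.csv", index=False)
        (out / "anova.json").write_text(json.dumps(anova, indent=2),
                                        encoding="utf-8")
        manifest.write(out / "manifest.json")
    return Study1Result(kept=kept, filter_report=report, runs=runs,
                        anova=anova, listings=listings, frame=frame,
                        manifest=manifest)


_STUDY2_CONTROLS = ["length", "old", "phon_neighbours", "bigram_freq",
                    "zipf", "prevalence", "concreteness", "familiarity",
                    "aoa", "pos"]


@dataclass
class Study2Config:
    seed: int = 0
    folds: int = 10
    repeats: int = 200
    kmax: int = 40
    hc_flavor: str = "HC2"
    controls: list[str] = field(default_factory=lambda: list(_STUDY2_CONTROLS))
    reference_levels: dict[str, str] = field(
        default_factory=lambda: {"pos": "noun"})
    exact_limit: int = 15
    outdir: Optional[str] = None


@dataclass
class Study2Result:
    frame: pd.DataFrame
    correlations: pd.DataFrame
    correlation_p: pd.DataFrame
    hierarchical: dict[str, object]
    manifest: RunManifest


def _typicality_frame(entries, inventory, config) -> tuple[pd.DataFrame, dict]:
    tc = TypicalityConfig(folds=config.folds, repeats=config.repeats,
                          seed=config.seed, kmax=config.kmax,
                          hc_flavor=config.hc_flavor,
                          exact_limit=config.exact_limit)
    runs = {dv: run_typicality(entries, inventory, dv, tc) for dv in DVS}
    return _entries_frame(entries, runs), runs


def run_study2(entries: Sequence[WordEntry],
               inventory: Optional[PhonemeInventory] = None,
               config: Study2Config | None = None) -> Study2Result:
    """Spearman matrix plus 3-step hierarchical regressions per affect DV:
    controls -> other two ratings -> typicality triplet.

    Expects a filtered lexicon with the control covariates merged.
    """
    config = config or Study2Config()
    inventory = inventory or load_inventory()
    entries = list(entries)
    numeric_controls = [c for c in config.controls if c != "pos"]
    missing = sorted({c for c in numeric_controls
                      for e in entries if c not in e.covariates})
    if missing:
        raise ValueError("missing covariate(s): " + ", ".join(missing))

    frame, runs = _typicality_frame(entries, inventory, config)
    cont = frame[numeric_controls + ["valence", "emotionality", "arousal",
                                     "typ_valence", "typ_emotionality",
                                     "typ_arousal"]]
    rho, pvals = spearman_matrix(cont)

    hier: dict[str, object] = {}
    for dv in DVS:
        others = [d for d in DVS if d != dv]
        steps = [("step1_controls", list(config.controls)),
                 ("step2_other_ratings", others),
                 ("step3_typicality", [f"typ_{d}" for d in DVS])]
        hier[dv] = hierarchical_regression(
            frame, dv, steps, hc_flavor=config.hc_flavor,
            reference_levels=config.reference_levels)

    manifest = RunManifest(
        config_hash=_config_hash(config.__dict__ | {"study": 2}),
        seed=config.seed, inventory_id=inventory.inventory_id,
        variable_roster=list(runs["valence"].screen.kept_columns),
        stage_rows={"input": len(entries)})

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        rho.to_csv(out / "spearman_rho.csv")
        pvals.to_csv(out / "spearman_p.csv")
        for dv, res in hier.items():
            _hier_table(res).to_csv(out / f"hier_{dv}.csv", index=False)
        manifest.write(out / "manifest.json")
    return Study2Result(frame=frame, correlations=rho, correlation_p=pvals,
                        hierarchical=hier, manifest=manifest)


def _hier_table(res) -> pd.DataFrame:
    rows = []
    for step in res.steps:
        rows.append({"step": step.label, "term": "", "estimate": np.nan,
                     "std_error": np.nan, "t": np.nan, "p": step.p_block,
                     "adjusted_r2": step.adjusted_r2,
                     "delta_r2": step.delta_r2})
        for rec in step.model.table():
            if rec["term"] in step.added_terms or step is res.steps[0]:
                rows.append({"step": step.label, **rec,
                             "adjusted_r2": np.nan, "delta_r2": np.nan})
    return pd.DataFrame(rows)


@dataclass
class Study3Config:
    seed: int = 0
    folds: int = 10
    repeats: int = 200
    kmax: int = 40
    hc_flavor: str = "HC2"
    controls: list[str] = field(default_factory=lambda: list(_STUDY2_CONTROLS))
    reference_levels: dict[str, str] = field(
        default_factory=lambda: {"pos": "noun"})
    dvs: tuple[str, ...] = ("rt", "error_rate")
    exact_limit: int = 15
    outdir: Optional[str] = None


@dataclass
class Study3Result:
    frame: pd.DataFrame
    hierarchical: dict[tuple[str, str], object]  # (dv, order) -> result
    manifest: RunManifest


def study3_steps(order: str, controls: Sequence[str]) -> list[tuple[str, list[str]]]:
    """5-step entry sequences for the item-level analyses.

    Order 'a': controls, affect ratings, their arousal interactions,
    typicality, typicality-arousal interactions. Order 'b' swaps the
    rating and typicality blocks.
    """
    affect = [("affect", ["valence", "emotionality", "arousal"]),
              ("affect_interactions", ["valence:arousal",
                                       "emotionality:arousal"])]
    typic = [("typicality", ["typ_valence", "typ_emotionality", "typ_arousal"]),
             ("typicality_interactions", ["typ_valence:arousal",
                                          "typ_emotionality:arousal"])]
    if order == "a":
        blocks = affect + typic
    elif order == "b":
        blocks = typic + affect
    else:
        raise ValueError("order must be 'a' or 'b'")
    steps = [("step1_controls", list(controls))]
    for i, (label, terms) in enumerate(blocks, start=2):
        steps.append((f"step{i}{order}_{label}", terms))
    return steps


def run_study3(entries: Sequence[WordEntry],
               inventory: Optional[PhonemeInventory] = None,
               config: Study3Config | None = None) -> Study3Result:
    """Item-level 5-step hierarchical regressions for RT and error-rate
    DVs, in both entry orders ('a' and 'b')."""
    config = config or Study3Config()
    inventory = inventory or load_inventory()
    entries = list(entries)
    for dv in config.dvs:
        if any(dv not in e.covariates for e in entries):
            raise ValueError(f"missing item-level column {dv!r}")
    s2 = Study2Config(seed=config.seed, folds=config.folds,
                      repeats=config.repeats, kmax=config.kmax,
                      hc_flavor=config.hc_flavor,
                      exact_limit=config.exact_limit)
    frame, runs = _typicality_frame(entries, inventory, s2)

    hier: dict[tuple[str, str], object] = {}
    for dv in config.dvs:
        for order in ("a", "b"):
            steps = study3_steps(order, config.controls)
            hier[(dv, order)] = hierarchical_regression(
                frame, dv, steps, hc_flavor=config.hc_flavor,
                reference_levels=config.reference_levels)

    manifest = RunManifest(
        config_hash=_config_hash({"study": 3, "seed": config.seed,
                                  "dvs": list(config.dvs)}),
        seed=config.seed, inventory_id=inventory.inventory_id,
        variable_roster=list(runs["valence"].screen.kept_columns),
        stage_rows={"input": len(entries)})

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for (dv, order), res in hier.items():
            _hier_table(res).to_csv(out / f"hier_{dv}_{order}.csv", index=False)
        manifest.write(out / "manifest.json")
    return Study3Result(frame=frame, hierarchical=hier, manifest=manifest)
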