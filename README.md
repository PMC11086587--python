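# formtypic

Phonological **form-typicality** analysis for affective lexicons, built for
Spanish-style phoneme inventories. The package turns a transcribed lexicon
with valence/arousal rating norms into per-word *form typicality* scores —
z-scored fitted values from a cross-validated best-subset regression of an
affective rating on phonological form variables — and provides the
surrounding statistics (rating-agreement filtering, Welch ANOVA by part of
speech with Games-Howell post hocs, Spearman matrices, and hierarchical
robust-SE regressions with ΔR²).

Everything runs offline on synthetic data: the `synth` module generates
phonotactically plausible lexicons with a multi-rater affect model and
*planted* form→rating effects at a configurable population R², so every
pipeline stage is testable without external rating norms.

## Modules

| module | contents |
| --- | --- |
| `formtypic.phonology` | 31-segment Castilian inventory (YAML-configurable), word encoding into an 83-variable form vector (feature counts, initial/final indicators, phoneme ids, stress position) |
| `formtypic.filters` | rating-agreement cutoff (SD < 1.5), POS exclusion, orthographic prefix stripping, emotionality = \|valence − 5\| |
| `formtypic.model` | predictor screening (zero variance + linear dependencies), exact/hybrid best-subset search, repeated k-fold CV selection (with per-fold re-selection and `best` / `one_se` rules), HC0–HC3 sandwich OLS, typicality scores |
| `formtypic.stats` | Bartlett, Welch ANOVA (+ω²), Games-Howell, pairwise-complete Spearman, hierarchical regressions with robust Wald block tests |
| `formtypic.synth` | synthetic lexicon generator, rater-mixture affect model with disagreement subpopulation, covariate/item-data helpers, packaged hand-transcribed fixture |
| `formtypic.io` | lexicon CSV reader/writer, run manifests, study-level drivers (`run_study1/2/3`) |

## CLI

```sh
formtypic simulate --n-words 2000 --seed 1 --out lexicon.csv
formtypic filter   --lexicon lexicon.csv --out kept.csv --report report.json
formtypic encode   --lexicon kept.csv --out form_matrix.csv
formtypic fit      --lexicon kept.csv --dv valence --repeats 200 --seed 1 \
                   --out model.csv --scores scores.csv --manifest run.json
formtypic anova    --scores scores.csv --group pos --out anova.json
formtypic hier     --data merged.csv --dv rt --steps steps.yaml --out hier.csv
formtypic study1   --lexicon lexicon.csv --outdir out/   # also study2, study3
```

Lexicon CSV columns: `word, transcription, stress_syllable, pos,
valence_mean, valence_sd, arousal_mean, arousal_sd[, covariates...]`, where
`transcription` is whitespace-separated phoneme symbols with `.` syllable
separators (e.g. `b a . l a`) and stress is a 1-based syllable index.

## Notes

- Phoneme numeric ids are assigned by inventory-config order; id-valued
  predictors are comparable only within one configuration.
- `cv_select` defaults to re-running the subset search inside each training
  fold (leakage-free); `selection_rule="one_se"` applies the one-standard-
  error parsimony rule for flat CV curves.
- Monosyllables are coded as final-stressed so the three stress categories
  partition all words.
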