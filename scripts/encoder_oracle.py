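#!/usr/bin/env python
"""Independent brute-force form-variable encoder.

Standalone oracle used to freeze expected encoder outputs for the fixture
lexicon. Deliberately shares no code with the formtypic package: it reads
the inventory YAML and lexicon CSV with the plain csv/yaml modules and
recomputes every variable with naive loops.

Usage:
    python scripts/encoder_oracle.py INVENTORY.yaml LEXICON.csv OUT.csv
"""

import csv
import sys

import yaml

CPLACES = ["bilabial", "labiodental", "dental", "alveolar", "palatal",
           "velar", "labiovelar"]
MANNERS = ["plosive", "nasal", "fricative", "affricate", "lateral",
           "trill", "tap", "approximant"]
VOICINGS = ["voiced", "voiceless"]
VPLACES = ["front", "central", "back"]
HEIGHTS = ["open", "mid", "close"]
ROUNDINGS = ["rounded", "unrounded"]


def header():
    cols = ["length_letters", "n_phonemes", "n_syllables",
            "initial_phoneme_id", "final_phoneme_id"]
    for scope in ["n", "init", "final"]:
        for group, cats in [("cplace", CPLACES), ("manner", MANNERS),
                            ("voicing", VOICINGS), ("vplace", VPLACES),
                            ("height", HEIGHTS), ("rounding", ROUNDINGS)]:
            for cat in cats:
                cols.append(scope + "_" + group + "_" + cat)
    cols += ["stress_initial", "stress_medial", "stress_final"]
    return cols


def categories(features):
    """List of roster category keys for one phoneme's feature dict."""
    keys = []
    if features["class"] == "vowel":
        keys.append("vplace_" + features["place"])
        keys.append("height_" + features["height"])
        keys.append("rounding_" + features["rounding"])
    else:
        keys.append("cplace_" + features["place"])
        keys.append("manner_" + features["manner"])
        keys.append("voicing_" + features["voicing"])
    return keys


def encode_row(word, transcription, stress, table, ids):
    phonemes = []
    n_syllables = 1
    for token in transcription.split():
        if token == ".":
            n_syllables += 1
        else:
            phonemes.append(token)

    out = {}
    for col in header():
        out[col] = 0.0
    out["length_letters"] = float(len(word))
    out["n_phonemes"] = float(len(phonemes))
    out["n_syllables"] = float(n_syllables)
    out["initial_phoneme_id"] = float(ids[phonemes[0]])
    out["final_phoneme_id"] = float(ids[phonemes[-1]])

    for symbol in phonemes:
        for key in categories(table[symbol]):
            out["n_" + key] = out["n_" + key] + 1.0
    for key in categories(table[phonemes[0]]):
        out["init_" + key] = 1.0
    for key in categories(table[phonemes[-1]]):
        out["final_" + key] = 1.0

    if n_syllables == 1 or stress == n_syllables:
        out["stress_final"] = 1.0
    elif stress == 1:
        out["stress_initial"] = 1.0
    else:
        out["stress_medial"] = 1.0
    return out


def main(inventory_path, lexicon_path, out_path):
    with open(inventory_path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    table = {}
    ids = {}
    number = 0
    for row in doc["phonemes"]:
        number += 1
        table[row["symbol"]] = row
        ids[row["symbol"]] = number

    cols = header()
    with open(lexicon_path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)

    with open(out_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["word"] + cols)
        for row in rows:
            vec = encode_row(row["word"], row["transcription"],
                             int(row["stress_syllable"]), table, ids)
            writer.writerow([row["word"]] + [repr(vec[c]) for c in cols])


if __name__ == "__main__":
    main(sys.argv[1], sys.argv[2], sys.argv[3])
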