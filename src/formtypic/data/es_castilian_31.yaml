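# Castilian Spanish segment inventory (31 entries).
# Numeric ids are assigned by listing order (1-based); edit order with care,
# since id-based predictors are only comparable within a single configuration.
id: es_castilian_31
phonemes:
  - {symbol: a, class: vowel, place: central, height: open, rounding: unrounded}
  - {symbol: e, class: vowel, place: front, height: mid, rounding: unrounded}
  - {symbol: i, class: vowel, place: front, height: close, rounding: unrounded}
  - {symbol: o, class: vowel, place: back, height: mid, rounding: rounded}
  - {symbol: u, class: vowel, place: back, height: close, rounding: rounded}
  - {symbol: p, class: consonant, place: bilabial, manner: plosive, voicing: voiceless}
  - {symbol: b, class: consonant, place: bilabial, manner: plosive, voicing: voiced}
  - {symbol: t, class: consonant, place: dental, manner: plosive, voicing: voiceless}
  - {symbol: d, class: consonant, place: dental, manner: plosive, voicing: voiced}
  - {symbol: k, class: consonant, place: velar, manner: plosive, voicing: voiceless}
  - {symbol: g, class: consonant, place: velar, manner: plosive, voicing: voiced}
  - {symbol: tʃ, class: consonant, place: palatal, manner: affricate, voicing: voiceless}
  - {symbol: f, class: consonant, place: labiodental, manner: fricative, voicing: voiceless}
  - {symbol: θ, class: consonant, place: dental, manner: fricative, voicing: voiceless}
  - {symbol: s, class: consonant, place: alveolar, manner: fricative, voicing: voiceless}
  - {symbol: z, class: consonant, place: alveolar, manner: fricative, voicing: voiced}
  - {symbol: ʝ, class: consonant, place: palatal, manner: fricative, voicing: voiced}
  - {symbol: x, class: consonant, place: velar, manner: fricative, voicing: voiceless}
  - {symbol: m, class: consonant, place: bilabial, manner: nasal, voicing: voiced}
  - {symbol: n, class: consonant, place: alveolar, manner: nasal, voicing: voiced}
  - {symbol: ɲ, class: consonant, place: palatal, manner: nasal, voicing: voiced}
  - {symbol: ŋ, class: consonant, place: velar, manner: nasal, voicing: voiced}
  - {symbol: l, class: consonant, place: alveolar, manner: lateral, voicing: voiced}
  - {symbol: ʎ, class: consonant, place: palatal, manner: lateral, voicing: voiced}
  - {symbol: r, class: consonant, place: alveolar, manner: trill, voicing: voiced}
  - {symbol: ɾ, class: consonant, place: alveolar, manner: tap, voicing: voiced}
  - {symbol: j, class: consonant, place: palatal, manner: approximant, voicing: voiced}
  - {symbol: w, class: consonant, place: labiovelar, manner: approximant, voicing: voiced}
  - {symbol: β, class: consonant, place: bilabial, manner: approximant, voicing: voiced}
  - {symbol: ð, class: consonant, place: dental, manner: approximant, voicing: voiced}
  - {symbol: ɣ, class: consonant, place: velar, manner: approximant, voicing: voiced}
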