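{
  "version": "film-ieq-24item-synthetic-map",
  "description": "Film Immersive Experience Questionnaire: 24 items scored by simple summation into four subscales (captivation, real-world dissociation, comprehension, transportation). The per-item allocation below is a synthetic stand-in following the instrument's published four-subscale structure and item counts; downstream scoring depends only on the partition, not on item wording.",
  "subscales": {
    "Cap": [1, 2, 3, 4, 5, 6, 7, 8, 9],
    "Dis": [10, 11, 12, 13, 14, 15],
    "Com": [16, 17, 18, 19],
    "Tra": [20, 21, 22, 23, 24]
  }
}
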