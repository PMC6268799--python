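{
  "name": "2B8",
  "alignment": 2,
  "grid_size": 1.0,
  "intercept": 8.34,
  "transcription_note": "the printed equation for this model contains stray formatting; coefficients were read from the legible numerals and should be verified against the journal PDF",
  "terms": [
    {"cell": [-3, 9, 4], "ipe": "any", "coef": -6.52},
    {"cell": [0, 10, 4], "ipe": "any", "coef": -9.04},
    {"cell": [0, 2, -1], "ipe": "any", "coef": -7.64},
    {"cell": [-1, -2, 11], "ipe": "any", "coef": -5.08},
    {"cell": [0, 1, -2], "ipe": "any", "coef": -9.03},
    {"cell": [-3, 8, 5], "ipe": "any", "coef": 5.37},
    {"cell": [0, 5, -3], "ipe": "any", "coef": -26.15},
    {"cell": [0, 2, 2], "ipe": "ar", "coef": 23.89}
  ]
}
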