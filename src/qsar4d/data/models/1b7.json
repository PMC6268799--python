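{
  "name": "1B7",
  "alignment": 1,
  "grid_size": 1.0,
  "intercept": 7.89,
  "terms": [
    {"cell": [2, 11, 4], "ipe": "any", "coef": -13.99},
    {"cell": [-1, 8, 2], "ipe": "any", "coef": -6.96},
    {"cell": [0, -2, 9], "ipe": "any", "coef": -2.04},
    {"cell": [1, 13, 1], "ipe": "any", "coef": 22.68},
    {"cell": [1, -1, 9], "ipe": "any", "coef": 12.16},
    {"cell": [1, 2, 2], "ipe": "ar", "coef": 1.84},
    {"cell": [1, 11, -2], "ipe": "any", "coef": 19.60}
  ]
}
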