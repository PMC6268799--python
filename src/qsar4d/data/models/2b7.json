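{
  "name": "2B7",
  "alignment": 2,
  "grid_size": 1.0,
  "intercept": 7.70,
  "terms": [
    {"cell": [-1, 9, 4], "ipe": "any", "coef": 2.47},
    {"cell": [0, 10, 4], "ipe": "any", "coef": -10.58},
    {"cell": [0, 7, -2], "ipe": "any", "coef": 8.22},
    {"cell": [-1, -2, 11], "ipe": "any", "coef": -5.27},
    {"cell": [0, 5, -3], "ipe": "any", "coef": -35.20},
    {"cell": [0, 2, 2], "ipe": "ar", "coef": 21.70},
    {"cell": [0, -1, 9], "ipe": "ar", "coef": 0.84}
  ]
}
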