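{
  "name": "2B9",
  "alignment": 2,
  "grid_size": 1.0,
  "intercept": 6.66,
  "terms": [
    {"cell": [-1, 12, 6], "ipe": "any", "coef": -30.48},
    {"cell": [1, 3, 6], "ipe": "hba", "coef": 10.92},
    {"cell": [0, 11, 3], "ipe": "p-", "coef": 16.70},
    {"cell": [0, 12, -1], "ipe": "any", "coef": -15.21},
    {"cell": [0, 10, -2], "ipe": "any", "coef": 14.18},
    {"cell": [0, 0, -2], "ipe": "any", "coef": 0.57},
    {"cell": [-1, -2, 11], "ipe": "any", "coef": -4.01},
    {"cell": [0, 2, 2], "ipe": "ar", "coef": 18.23},
    {"cell": [2, 5, 0], "ipe": "any", "coef": -25.70}
  ]
}
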