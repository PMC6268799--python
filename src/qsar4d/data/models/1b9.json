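{
  "name": "1B9",
  "alignment": 1,
  "grid_size": 1.0,
  "intercept": 8.19,
  "terms": [
    {"cell": [2, 11, 4], "ipe": "any", "coef": -18.84},
    {"cell": [0, -2, -1], "ipe": "any", "coef": -6.13},
    {"cell": [0, 1, -2], "ipe": "any", "coef": 8.45},
    {"cell": [0, 11, 5], "ipe": "any", "coef": -8.71},
    {"cell": [-1, 8, 2], "ipe": "any", "coef": -7.54},
    {"cell": [1, 6, -2], "ipe": "np", "coef": -20.98},
    {"cell": [1, 13, 1], "ipe": "any", "coef": 15.96},
    {"cell": [1, 2, 0], "ipe": "any", "coef": 3.93},
    {"cell": [0, 0, -2], "ipe": "any", "coef": 1.61}
  ]
}
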