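id,pic50_exp,calc_1B9,res_1B9,calc_2B9,res_2B9
1,9.70,9.84,0.14,9.27,-0.43
2,9.52,9.09,-0.43,8.11,-1.41
3,9.15,9.30,0.15,9.48,0.33
4,9.10,8.77,-0.33,9.04,-0.06
5,9.00,9.16,0.16,8.97,-0.03
6,9.00,8.49,-0.51,8.81,-0.19
7,8.70,8.57,-0.13,8.89,0.19
8,8.70,8.24,-0.46,8.32,-0.38
9,8.64,7.83,-0.81,8.83,0.19
10,8.64,8.45,-0.19,8.97,0.33
11,8.60,8.01,-0.59,8.32,-0.28
12,8.60,8.08,-0.52,8.59,-0.01
13,8.52,7.86,-0.66,8.47,-0.05
14,8.30,8.38,0.08,7.88,-0.42
15,8.15,8.09,-0.06,7.97,-0.18
16,8.00,8.39,0.39,7.86,-0.14
17,8.00,8.25,0.25,7.45,-0.55
18,7.70,7.85,0.15,7.76,0.06
19,7.70,7.41,-0.29,6.92,-0.78
20,7.52,7.81,0.29,7.58,0.06
21,7.52,7.62,0.10,7.41,-0.11
22,7.49,7.73,0.24,7.14,-0.35
23,7.46,7.10,-0.36,6.87,-0.59
24,7.40,7.46,0.06,7.86,0.46
25,7.30,7.89,0.59,7.28,-0.02
26,7.30,7.68,0.38,7.11,-0.19
27,7.30,6.93,-0.37,7.19,-0.11
28,7.22,6.76,-0.46,7.01,-0.21
29,7.00,7.08,0.08,6.45,-0.55
30,7.00,6.73,-0.27,6.59,-0.41
31,7.00,7.31,0.31,7.46,0.46
32,7.00,7.64,0.64,7.47,0.47
33,7.00,7.71,0.71,7.60,0.60
34,7.00,6.37,-0.63,6.86,-0.14
35,6.72,6.08,-0.64,6.27,-0.45
36,6.70,6.84,0.14,6.33,-0.37
37,6.60,6.53,-0.07,7.01,0.41
38,6.52,6.39,-0.13,6.91,0.39
39,6.52,6.02,-0.50,6.40,-0.12
40,6.52,6.63,0.11,6.32,-0.20
41,6.52,6.97,0.45,6.57,0.05
42,6.49,6.77,0.28,6.58,0.09
43,6.46,6.09,-0.37,6.39,-0.07
44,6.46,6.56,0.10,6.76,0.30
45,6.40,7.01,0.61,6.26,-0.14
46,6.30,6.15,-0.15,6.07,-0.23
47,6.30,6.18,-0.12,6.45,0.15
48,6.30,6.65,0.35,6.52,0.22
49,6.30,6.27,-0.03,7.44,1.14
50,6.22,6.43,0.21,6.40,0.18
51,6.00,7.12,1.12,7.14,1.14
52,6.00,6.46,0.46,7.05,1.05
53,6.00,6.17,0.17,6.28,0.28
54,6.00,6.39,0.39,6.61,0.61
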