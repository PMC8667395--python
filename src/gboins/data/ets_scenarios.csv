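scenario,mtd,dose,g01,g2,g3,g4
1,4,1,0.83,0.12,0.04,0.01
1,4,2,0.75,0.15,0.07,0.03
1,4,3,0.62,0.18,0.11,0.09
1,4,4,0.51,0.19,0.14,0.16
1,4,5,0.34,0.16,0.15,0.35
1,4,6,0.19,0.11,0.11,0.59
2,4,1,0.92,0.03,0.03,0.02
2,4,2,0.85,0.05,0.07,0.03
2,4,3,0.70,0.10,0.14,0.06
2,4,4,0.55,0.15,0.21,0.09
2,4,5,0.24,0.26,0.35,0.15
2,4,6,0.00,0.36,0.49,0.21
3,2,1,0.78,0.14,0.06,0.02
3,2,2,0.56,0.19,0.12,0.12
3,2,3,0.50,0.18,0.14,0.18
3,2,4,0.40,0.17,0.15,0.28
3,2,5,0.30,0.15,0.14,0.41
3,2,6,0.16,0.09,0.10,0.65
4,3,1,0.88,0.04,0.06,0.02
4,3,2,0.64,0.12,0.17,0.07
4,3,3,0.52,0.16,0.22,0.10
4,3,4,0.35,0.22,0.30,0.13
4,3,5,0.17,0.28,0.38,0.17
4,3,6,0.00,0.39,0.52,0.23
5,6,1,1.00,0.00,0.00,0.00
5,6,2,0.91,0.06,0.03,0.00
5,6,3,0.88,0.07,0.04,0.01
5,6,4,0.86,0.08,0.05,0.01
5,6,5,0.80,0.10,0.08,0.02
5,6,6,0.65,0.13,0.14,0.08
6,1,1,0.50,0.25,0.11,0.14
6,1,2,0.38,0.24,0.12,0.26
6,1,3,0.29,0.21,0.12,0.38
6,1,4,0.19,0.16,0.10,0.55
6,1,5,0.13,0.11,0.08,0.68
6,1,6,0.08,0.07,0.05,0.80
7,2,1,0.78,0.14,0.00,0.08
7,2,2,0.58,0.18,0.00,0.24
7,2,3,0.50,0.18,0.00,0.32
7,2,4,0.40,0.17,0.00,0.43
7,2,5,0.30,0.15,0.00,0.55
7,2,6,0.16,0.09,0.00,0.75
8,4,1,0.92,0.00,0.08,0.00
8,4,2,0.76,0.00,0.24,0.00
8,4,3,0.68,0.00,0.32,0.00
8,4,4,0.57,0.00,0.43,0.00
8,4,5,0.45,0.00,0.55,0.00
8,4,6,0.25,0.00,0.75,0.00
9,2,1,0.66,0.34,0.00,0.00
9,2,2,0.10,0.90,0.00,0.00
9,2,3,0.00,0.86,0.14,0.00
9,2,4,0.00,0.54,0.46,0.00
9,2,5,0.00,0.20,0.80,0.00
9,2,6,0.00,0.33,0.00,0.67
10,4,1,0.84,0.16,0.00,0.00
10,4,2,0.52,0.48,0.00,0.00
10,4,3,0.36,0.64,0.00,0.00
10,4,4,0.14,0.86,0.00,0.00
10,4,5,0.45,0.00,0.55,0.00
10,4,6,0.25,0.00,0.75,0.00
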