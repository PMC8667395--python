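target,scenario,p1,p2,p3,p4,p5,mtd
0.2,1,0.20,0.25,0.35,0.45,0.50,1
0.2,2,0.20,0.30,0.40,0.50,0.60,1
0.2,3,0.15,0.20,0.25,0.35,0.45,2
0.2,4,0.15,0.20,0.30,0.45,0.55,2
0.2,5,0.10,0.20,0.25,0.35,0.45,2
0.2,6,0.10,0.20,0.30,0.40,0.55,2
0.2,7,0.08,0.15,0.20,0.25,0.35,3
0.2,8,0.08,0.15,0.20,0.30,0.45,3
0.2,9,0.05,0.10,0.20,0.25,0.35,3
0.2,10,0.05,0.10,0.20,0.30,0.45,3
0.2,11,0.05,0.10,0.15,0.20,0.25,4
0.2,12,0.05,0.10,0.15,0.20,0.30,4
0.2,13,0.02,0.06,0.10,0.20,0.25,4
0.2,14,0.02,0.06,0.10,0.20,0.30,4
0.2,15,0.02,0.05,0.07,0.10,0.20,5
0.2,16,0.01,0.06,0.10,0.15,0.20,5
0.3,1,0.30,0.40,0.50,0.60,0.70,1
0.3,2,0.30,0.45,0.60,0.70,0.80,1
0.3,3,0.20,0.30,0.40,0.50,0.60,2
0.3,4,0.20,0.30,0.45,0.60,0.70,2
0.3,5,0.15,0.30,0.40,0.50,0.60,2
0.3,6,0.15,0.30,0.45,0.60,0.70,2
0.3,7,0.12,0.20,0.30,0.40,0.50,3
0.3,8,0.12,0.20,0.30,0.45,0.60,3
0.3,9,0.05,0.15,0.30,0.40,0.50,3
0.3,10,0.05,0.15,0.30,0.45,0.60,3
0.3,11,0.05,0.12,0.20,0.30,0.40,4
0.3,12,0.05,0.12,0.20,0.30,0.45,4
0.3,13,0.02,0.08,0.15,0.30,0.40,4
0.3,14,0.02,0.08,0.15,0.30,0.45,4
0.3,15,0.02,0.10,0.15,0.20,0.30,5
0.3,16,0.01,0.04,0.08,0.15,0.30,5
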