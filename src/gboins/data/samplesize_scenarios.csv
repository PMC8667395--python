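target,scenario,p1,p2,p3,p4,p5,mtd
0.2,1,0.01,0.10,0.20,0.30,0.35,3
0.2,2,0.01,0.18,0.20,0.30,0.35,3
0.3,3,0.01,0.20,0.30,0.40,0.50,3
0.3,4,0.01,0.25,0.30,0.40,0.50,3
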