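S1_uM,S2_uM,period_s,sem_s
2.5,5,92.3,4.6
1.25,2.5,90.8,4.4
1,2,89.4,6.4
0.75,1.5,76.8,4.6
0.625,1.25,73.1,3.8
0.5,1,68.7,3.9
0.3125,0.625,64.2,3.7
0.125,0.25,61.1,3.1
0.0625,0.125,59.6,2.5
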