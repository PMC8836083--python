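S1_uM,S2_uM,period_s,sem_s
0,10,122,6.6
0,5,111,6.2
0,2.5,60.8,4.0
0,2,56.5,2.7
0,1.25,55.4,3.5
0,1,53.5,2.9
0,0.625,44.1,3.3
0,0.5,38.8,1.3
0,0.25,35.9,1.3
0,0.125,34.4,2
5,0,73.4,4.3
2.5,0,61.9,3.5
1.25,0,54.2,2.5
1,0,52.7,2
0.625,0,48.2,2.4
0.5,0,47.1,1.5
0.3125,0,41.9,2.6
0.25,0,41.8,1.4
0.125,0,39.8,1.4
0.0625,0,38.6,2.2
0,0,32.8,1.2
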