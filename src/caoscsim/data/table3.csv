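S1_uM,S2_uM,parameter,baseline,p_value,prcc
0.5,1.0,k_f,3.9,0.643,0.034
0.5,1.0,alpha1,0.385,1.44e-50,-0.831
0.5,1.0,c1,0.51,0.272,0.079
0.5,1.0,c2,1,1.74e-46,0.812
0.5,1.0,c3,0.76,4.6e-16,-0.541
0.5,1.0,k1,0.34,0.061,-0.1353
0.5,1.0,k2,0.6,4.01e-12,-0.4724
0.5,1.0,k3,0.8,8.45e-8,0.3740
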