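Q_LPM,F_D_N,C_D
1.9,2.72e-4,0.480
2.8,6.41e-4,0.522
4.2,1.52e-3,0.547
6.3,3.38e-3,0.543
10.0,8.75e-3,0.557
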