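time_h,dose_Gy,phase,delta,err
6,2,G1,-0.17,0.05
6,2,S,-0.15,0.08
6,2,G2,2.19,0.06
6,2,M,-0.68,0.01
6,5,G1,-0.17,0.07
6,5,S,-0.18,0.10
6,5,G2,2.39,0.09
6,5,M,-0.97,0.01
16,2,G1,0.32,0.08
16,2,S,-0.92,0.06
16,2,G2,0.64,0.07
16,2,M,-0.57,0.01
16,5,G1,-0.03,0.12
16,5,S,-0.96,0.06
16,5,G2,3.12,0.12
16,5,M,-0.54,0.01
24,2,G1,0.30,0.11
24,2,S,-0.89,0.08
24,2,G2,0.32,0.08
24,2,M,-0.87,0.01
24,5,G1,0.04,0.14
24,5,S,-0.95,0.08
24,5,G2,3.17,0.11
24,5,M,-0.90,0.01
48,2,G1,0.10,0.04
48,2,S,-0.65,0.04
48,2,G2,0.35,0.06
48,2,M,-0.74,0.01
48,5,G1,0.04,0.12
48,5,S,-0.88,0.03
48,5,G2,1.88,0.13
48,5,M,-0.90,0.01
72,2,G1,0.04,0.03
72,2,S,-0.46,0.06
72,2,G2,1.11,0.06
72,2,M,-0.39,0.003
72,5,G1,-0.03,0.10
72,5,S,-0.81,0.05
72,5,G2,4.17,0.13
72,5,M,-0.82,0.003
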