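time_h,dose_Gy,phase,percent,sem
0,0,G1,58.26,1.64
0,0,S,31.25,0.48
0,0,G2,9.35,1.08
0,0,M,1.132,0.432
6,0,G1,55.30,0.95
6,0,S,37.08,1.42
6,0,G2,7.04,0.81
6,0,M,0.582,0.183
6,2,G1,45.78,0.96
6,2,S,31.56,1.38
6,2,G2,22.47,1.60
6,2,M,0.189,0.076
6,5,G1,45.63,1.89
6,5,S,30.51,2.29
6,5,G2,23.84,2.81
6,5,M,0.018,0.008
16,0,G1,62.62,1.47
16,0,S,27.38,1.56
16,0,G2,9.12,1.13
16,0,M,0.883,0.226
16,2,G1,82.37,1.43
16,2,S,2.32,0.33
16,2,G2,14.91,1.68
16,2,M,0.377,0.118
16,5,G1,60.82,3.15
16,5,S,1.23,0.34
16,5,G2,37.54,3.49
16,5,M,0.409,0.054
24,0,G1,68.05,2.09
24,0,S,24.57,2.12
24,0,G2,6.77,0.99
24,0,M,0.600,0.184
24,2,G1,88.23,1.68
24,2,S,2.78,0.37
24,2,G2,8.91,2.03
24,2,M,0.077,0.021
24,5,G1,70.50,3.30
24,5,S,1.17,0.43
24,5,G2,28.26,3.42
24,5,M,0.062,0.021
48,0,G1,79.65,0.69
48,0,S,14.68,0.62
48,0,G2,5.35,0.60
48,0,M,0.319,0.150
48,2,G1,87.49,0.71
48,2,S,5.17,1.07
48,2,G2,7.25,1.75
48,2,M,0.084,0.044
48,5,G1,82.75,3.96
48,5,S,1.79,0.54
48,5,G2,15.42,4.50
48,5,M,0.031,0.010
72,0,G1,79.02,0.46
72,0,S,16.84,0.40
72,0,G2,3.86,0.54
72,0,M,0.279,0.086
72,2,G1,82.52,0.67
72,2,S,9.16,1.97
72,2,G2,8.15,1.94
72,2,M,0.171,0.059
72,5,G1,76.80,3.77
72,5,S,3.20,1.47
72,5,G2,19.95,4.72
72,5,M,0.051,0.023
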