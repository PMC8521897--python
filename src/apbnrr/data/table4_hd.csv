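case,type,HD_RR,HD_BSPLINE,HD_PBNRR,HD_APBNRR,iterations
1,BS,11.07,9.30,7.63,3.48,2
2,BS,24.64,24.51,21.39,2.77,5
3,BS,10.49,7.75,10.53,5.88,3
4,BS,6.59,6.51,4.97,2.64,2
5,BS,7.68,5.28,5.73,2.65,2
6,BS,8.54,8.54,5.55,3.48,2
7,BS,8.99,8.99,7.36,4.33,3
8,PR,17.00,17.00,16.49,5.69,4
9,PR,10.59,5.28,10.76,2.30,3
10,PR,16.15,13.78,15.12,4.60,7
11,PR,26.89,15.86,26.89,4.00,6
12,PR,29.93,21.34,27.76,2.83,7
13,TR,25.51,25.18,22.50,4.97,4
14,TR,5.59,5.59,3.43,3.09,1
15,TR,17.90,16.94,15.56,4.11,9
16,TR,18.85,17.49,17.38,3.57,3
17,TR,17.14,7.48,15.41,4.25,2
18,TR,25.72,25.72,23.90,3.42,6
19,TR,25.43,17.63,25.22,3.30,9
20,TR,23.61,21.42,22.89,3.66,4
21,TR,19.24,14.61,19.89,2.40,6
22,TR,30.37,21.39,28.96,3.13,7
23,TR,15.16,11.89,13.96,3.15,4
24,TR,13.47,8.90,13.66,3.28,4
25,TR,23.22,14.99,21.44,3.08,9
26,STR,17.59,17.12,16.63,4.19,5
27,STR,35.72,27.77,33.57,3.71,8
28,STR,32.32,29.43,30.13,3.45,6
29,STR,18.48,13.30,18.15,3.97,4
30,STR,27.07,15.55,24.91,3.54,7
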