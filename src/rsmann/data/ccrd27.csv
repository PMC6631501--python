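run,temperature,ethanol,ls_ratio,power,yield,yield_sd,rsm_pred,rsm_dev,ann_pred,ann_dev
1,40,65,20,105,20.75,3.60,25.45,4.70,20.77,0.02
2,60,65,20,105,39.41,1.31,34.99,4.42,39.37,0.04
3,40,85,20,105,18.70,1.92,20.01,1.30,18.70,0.01
4,60,85,20,105,35.23,1.74,32.99,2.24,35.24,0.00
5,40,65,40,105,38.02,3.10,40.56,2.55,38.01,0.00
6,60,65,40,105,39.84,2.06,43.18,3.33,41.49,1.65
7,40,85,40,105,34.12,2.26,30.11,4.01,34.12,0.00
8,60,85,40,105,37.67,2.00,36.16,1.51,37.66,0.01
9,40,65,20,135,30.65,1.29,32.23,1.58,30.64,0.00
10,60,65,20,135,30.44,4.18,34.82,4.39,30.84,0.40
11,40,85,20,135,29.68,3.48,26.72,2.96,29.66,0.01
12,60,85,20,135,35.23,2.62,32.75,2.48,35.24,0.01
13,40,65,40,135,40.74,1.79,43.36,2.62,43.92,3.19
14,60,65,40,135,40.25,2.78,39.02,1.23,40.62,0.37
15,40,85,40,135,28.33,3.10,32.83,4.50,28.32,0.01
16,60,85,40,135,36.25,0.74,31.94,4.32,35.93,0.32
17,30,75,30,120,37.59,1.16,32.67,4.92,37.94,0.36
18,70,75,30,120,36.85,1.17,41.31,4.47,36.84,0.01
19,50,55,30,120,38.32,0.77,31.79,6.53,38.32,0.00
20,50,95,30,120,13.18,2.34,19.26,6.08,13.18,0.00
21,50,75,10,120,26.31,0.95,26.60,0.29,26.33,0.01
22,50,75,50,120,41.64,2.47,40.90,0.74,41.65,0.01
23,50,75,30,90,36.35,1.39,36.73,0.38,36.36,0.00
24,50,75,30,150,40.12,1.57,39.29,0.83,38.58,1.54
25,50,75,30,120,39.78,2.38,39.92,0.14,39.89,0.12
26,50,75,30,120,39.99,2.33,39.92,0.07,39.89,0.10
27,50,75,30,120,39.98,0.35,39.92,0.07,39.89,0.09
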