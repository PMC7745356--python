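sum_score,Guatemala,Belagavi,Nagpur,Pakistan,DRC,Kenya,Zambia
0,0.00,0.00,0.00,0.00,0.00,0.00,0.00
1,7.12,4.66,6.39,6.27,6.24,8.38,13.08
2,19.20,17.73,15.87,17.01,16.18,24.61,25.59
3,31.71,30.25,27.45,31.28,24.98,40.45,38.92
4,42.19,40.57,37.83,43.68,33.76,52.63,48.94
5,51.42,50.00,46.74,52.81,43.72,60.67,57.09
6,61.04,59.91,56.12,61.68,53.96,68.03,66.32
7,71.44,70.53,67.05,72.00,64.36,76.31,76.46
8,82.01,81.37,78.76,83.43,76.19,84.98,86.22
9,92.15,91.88,89.64,94.62,88.69,93.44,93.83
10,100.00,100.00,100.00,100.00,100.00,100.00,100.00
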