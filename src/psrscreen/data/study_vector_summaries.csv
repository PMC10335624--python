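patient,vector,mean_tr,sd_tr,n_over,n_below,frt_pct,mean_score,sd_score,evt_pct
01,alternate,0.274,0.078,2045,6565,76.25,4.6,9.7,0
01,primary,0.057,0.064,28,8582,99.67,385.0,76.2,100
02,alternate,0.075,0.062,5,8785,99.94,40.9,24.5,2.4
02,primary,0.175,0.064,84,8706,99.04,25.6,33.2,2.62
03,alternate,0.045,0.047,4,8686,99.95,57.0,40.6,14.32
03,primary,0.110,0.107,411,8279,95.27,807.5,522.1,81
04,alternate,0.199,0.138,980,7630,88.62,1.0,2.0,0
04,primary,0.164,0.107,545,8065,93.67,120.0,137.2,47
05,alternate,0.113,0.076,20,8590,99.77,40.7,27.0,2.68
05,primary,0.102,0.046,10,8600,99.88,536.6,282.0,100
06,alternate,0.363,0.180,4902,3708,43.07,0.2,0.9,0
06,primary,0.187,0.098,414,8196,95.19,201.0,286.9,43
07,alternate,0.297,0.139,4003,4607,53.51,5.1,7.7,0.29
07,primary,0.479,0.026,8605,5,0.06,3.9,11.8,0.07
08,alternate,0.382,0.059,6949,1740,20.03,9.6,16.6,0
08,primary,0.311,0.032,1420,7269,83.66,386.1,217.3,73
09,alternate,0.338,0.023,4778,3832,44.51,296.5,230.5,57.25
09,primary,0.168,0.031,10,8600,99.88,1046.8,262.0,99
10,alternate,0.048,0.040,0,8610,100,989.1,218.5,100
10,primary,0.153,0.049,2,8608,99.98,453.7,224.1,97
11,alternate,0.260,0.139,3452,5158,59.91,3.1,4.9,0
11,primary,0.203,0.088,410,8200,95.24,314.1,261.8,79
12,alternate,0.381,0.060,7346,1264,14.68,4.5,4.7,0
12,primary,0.195,0.027,0,8610,100,1161.9,211.7,100
13,alternate,0.203,0.107,944,6760,87.75,17.7,33.5,5.48
13,primary,0.340,0.107,2891,4813,62.47,247.3,263.4,61
14,alternate,0.142,0.070,168,8442,98.05,7.9,20.2,0.22
14,primary,0.143,0.105,413,8197,95.20,87.1,150.0,21
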