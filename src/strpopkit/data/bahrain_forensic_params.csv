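Parameter,D3S1358,VWA,D16S539,CSF1PO,TPOX,D8S1179,D21S11,D18S51,D2S441,D19S433,TH01,FGA,D22S1045,D5S818,D13S317,D7S820,SE33,D10S1248,D1S1656,D12S391,D2S1338
PM,0.9068,0.9334,0.9136,0.8786,0.8441,0.9477,0.9580,0.9682,0.9105,0.9591,0.9206,0.9689,0.8886,0.8967,0.9201,0.9290,0.9937,0.9139,0.9726,0.9738,0.9720
PD,0.9068,0.9334,0.9136,0.8786,0.8441,0.9477,0.9580,0.9682,0.9105,0.9591,0.9206,0.9689,0.8886,0.8967,0.9201,0.9290,0.9937,0.9139,0.9726,0.9738,0.9720
PE,0.5841,0.5410,0.4996,0.4965,0.3839,0.6358,0.6570,0.7001,0.4660,0.6784,0.5410,0.7703,0.4532,0.5153,0.5508,0.6080,0.8381,0.5977,0.6965,0.6965,0.7258
TPI,2.4027,2.1548,1.9532,1.9393,1.5168,2.7704,2.9511,3.3938,1.8100,3.1570,2.1548,4.4508,1.7597,2.0261,2.2073,2.5613,6.3140,2.4908,3.3519,3.3519,3.7192
PIC,0.7324,0.7730,0.7353,0.6829,0.6215,0.8051,0.8282,0.8566,0.7271,0.8349,0.7531,0.8596,0.6877,0.7173,0.7500,0.7718,0.9466,0.7489,0.8667,0.8696,0.8661
Ho,0.7919,0.7680,0.7440,0.7422,0.6703,0.8195,0.8306,0.8527,0.7238,0.8416,0.7680,0.8877,0.7159,0.7532,0.7735,0.8048,0.9208,0.7993,0.8508,0.8508,0.8656
HWE,0.0230,0.4470,0.3390,0.3210,0.3220,0.4790,0.2910,0.1490,0.2680,0.0350,0.3100,0.6620,0.2200,0.0230,0.3060,0.2420,0.3720,0.1380,0.5960,0.4300,0.1350
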