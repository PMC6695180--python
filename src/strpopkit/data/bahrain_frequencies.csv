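Allele,D3S1358,VWA,D16S539,CSF1PO,TPOX,D8S1179,D21S11,D18S51,D2S441,D19S433,TH01,FGA,D22S1045,D5S818,D13S317,D7S820,SE33,D10S1248,D1S1656,D12S391,D2S1338
6,,,,,0.01197,,,,,,0.27624,,,0.00092,,,,,,,
6.3,,,,,,,,,,,,,,,,,0.00645,,,,
7,,,,0.00737,0.00368,,,,,,0.24217,,,0.00184,0.00737,0.02947,,,,,
8,,,0.03039,0.01473,0.49632,0.00645,,,,,0.12523,,,0.02026,0.12707,0.18416,0.00737,,,,
9,,,0.13996,0.02302,0.14825,0.00645,,,0.00368,,0.21363,,,0.06262,0.04880,0.07090,0.00184,0.01013,,,
9.1,,,,0.00092,,,,,,,,,,,,0.00092,,,,,
9.3,,,,,,,,,,,0.12983,,,,,,,,,,
10,,,0.08379,0.27808,0.07182,0.06077,,0.00552,0.14549,0.00368,0.01197,,0.00830,0.09853,0.05985,0.28453,0.00092,0.00092,0.00184,,
10.3,,,,,,,,,,,0.00092,,,,,,,,,,
11,,0.00092,0.37569,0.30847,0.24125,0.09300,,0.02210,0.35175,0.02210,,,0.14945,0.27532,0.25967,0.22284,0.00184,0.01473,0.09576,,
11.2,,,,,,,,,,0.00092,,,,,,,0.00092,,,,
11.3,,,,,,,,,0.05985,,,,,,,,,,,,
12,,,0.19521,0.30295,0.02670,0.14457,,0.12155,0.08564,0.09024,,,0.01937,0.35267,0.33702,0.16759,0.00276,0.03131,0.13076,,
12.2,,,,,,,,,,0.01289,,,,,,,0.00184,,,,
12.3,,,,,,,,,0.00737,,,,,,,,,,,,
13,0.00276,0.00552,0.16114,0.05801,,0.24678,,0.14825,0.02394,0.21271,,,0.00554,0.17495,0.12431,0.02762,0.01657,0.21455,0.08471,,
13.2,,,,,,,,0.00184,,0.02670,,,,,,,0.00368,,,,
14,0.07182,0.08103,0.01381,0.00552,,0.22652,,0.20994,0.28361,0.24033,,,0.06919,0.01105,0.03315,0.01105,0.02578,0.30847,0.11971,,0.00184
14.2,,,,,,,,,,0.06169,,,,,,,0.00460,,,,
14.3,,,,,,,,,,,,,,,,,,,0.00368,,
15,0.23849,0.17127,,0.00092,,0.15838,,0.11326,0.03867,0.14088,,,0.41697,0.00184,0.00276,0.00092,0.01565,0.23665,0.16943,0.02394,
15.2,,,,,,,,,,0.09300,,,,,,,0.00184,,,,
15.3,,,,,,,,,,,,,,,,,0.00829,,0.03959,,
16,0.29834,0.25506,,,,0.04236,,0.13812,,0.05709,,0.00092,0.25830,,,,0.05709,0.13352,0.19337,0.02394,0.03223
16.1,,,,,,,,,,,,0.00092,,,,,,,,,
16.2,,,,,,,,,,0.02670,,,,,,,0.00092,,,,
16.3,,,,,,,,,,,,,,,,,,,0.04236,,
17,0.25599,0.25322,,,,0.01381,,0.10129,,0.00184,,0.00276,0.06919,,,,0.08564,0.04236,0.04788,0.13444,0.18508
17.2,,,,,,,,0.00092,,0.00645,,,,,,,,,,,
17.3,,,,,,,,,,,,,,,,,,,0.03959,0.00368,
18,0.11602,0.17403,,,,0.00092,,0.06169,,,,0.01013,0.00277,,,,0.09024,0.00737,0.00460,0.19337,0.10221
18.2,,,,,,,,,,0.00276,,0.00092,,,,,,,,,
18.3,,,,,,,,,,,,,,,,,,,0.01473,0.00737,
19,0.01381,0.04972,,,,,,0.04696,,,,0.06906,,,,,0.08748,,0.00092,0.10958,0.15009
19.1,,,,,,,,,,,,,,,,,,,,0.00184,
19.2,,,,,,,,,,,,0.01013,,,,,0.00184,,,,
19.3,,,,,,,,,,,,,,,,,,,0.01013,0.00276,
20,0.00276,0.00921,,,,,,0.01473,,,,0.08656,0.00092,,,,0.05157,,,0.11050,0.15193
20.2,,,,,,,,,,,,0.00092,,,,,0.00460,,,,
20.3,,,,,,,,,,,,,,,,,,,0.00092,0.00092,
21,,,,,,,,0.00552,,,,0.15285,,,,,0.02855,,,0.13352,0.06077
21.1,,,,,,,,,,,,,,,,,0.00276,,,,
21.2,,,,,,,,,,,,0.00829,,,,,0.01565,,,,
22,,,,,,,,0.00737,,,,0.15101,,,,,0.01105,,,0.10497,0.04696
22.2,,,,,,,,,,,,0.00921,,,,,0.02210,,,,
23,,,,,,,,0.00092,,,,0.18416,,,,,0.00184,,,0.08379,0.11971
23.2,,,,,,,,,,,,0.00276,,,,,0.01934,,,,
23.3,,,,,,,,,,,,0.00092,,,,,,,,,
24,,,,,,,,,,,,0.15654,,,,,0.00092,,,0.03959,0.08471
24.2,,,,,,,,,,,,0.00368,,,,,0.02670,,,,
25,,,,,,,,,,,,0.09024,,,,,,,,0.02118,0.05341
25.2,,,,,,,,,,,,,,,,,0.04052,,,,
26,,,,,,,0.00184,,,,,0.04144,,,,,,,,0.00460,0.01013
26.2,,,,,,,,,,,,0.00092,,,,,0.04696,,,,
27,,,,,,,0.02855,,,,,0.01013,,,,,,,,,0.00092
27.2,,,,,,,,,,,,,,,,,0.05157,,,,
28,,,,,,,0.16298,,,,,0.00276,,,,,,,,,
28.2,,,,,,,,,,,,,,,,,0.05617,,,,
29,,,,,,,0.24217,,,,,0.00184,,,,,,,,,
29.2,,,,,,,0.00092,,,,,,,,,,0.04972,,,,
30,,,,,,,0.18140,,,,,0.00092,,,,,,,,,
30.2,,,,,,,0.02762,,,,,,,,,,0.05709,,,,
31,,,,,,,0.05157,,,,,,,,,,,,,,
31.2,,,,,,,0.10221,,,,,,,,,,0.04144,,,,
32,,,,,,,0.00737,,,,,,,,,,0.00092,,,,
32.2,,,,,,,0.14088,,,,,,,,,,0.02394,,,,
33,,,,,,,,,,,,,,,,,0.00092,,,,
33.1,,,,,,,0.00092,,,,,,,,,,,,,,
33.2,,,,,,,0.03315,,,,,,,,,,0.00645,,,,
34,,,,,,,0.00368,,,,,,,,,,0.00092,,,,
34.2,,,,,,,0.00737,,,,,,,,,,0.00829,,,,
35,,,,,,,0.00184,,,,,,,,,,0.00184,,,,
35.2,,,,,,,0.00092,,,,,,,,,,,,,,
36,,,,,,,0.00184,,,,,,,,,,0.00368,,,,
37,,,,,,,0.00276,,,,,,,,,,0.00092,,,,
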