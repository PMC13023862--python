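participant	d
1	0.190
2	0.153
3	0.263
4	0.886
5	-0.156
6	-0.538
7	0.011
8	-0.209
9	0.012
10	0.364
11	0.207
12	-0.227
13	-0.019
14	0.081
15	0.093
16	-0.041
17	-0.004
18	0.020
19	0.113
20	0.042
21	0.212
22	-0.132
23	-0.074
24	0.013
25	-0.110
26	0.260
27	0.008
28	-0.083
29	0.007
30	-0.114
31	0.171
32	0.175
33	-0.073
34	0.026
35	0.062
36	0.044
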