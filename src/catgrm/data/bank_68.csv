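item_id,model,n_categories,a,b1,b2,b3,b4
1,GRM,4,0.98,-0.32,2.04,3.04,
2,GRM,4,0.83,-0.3,1.68,2.67,
3,GRM,4,0.9,-0.82,1.01,2.12,
4,GRM,4,1.02,-0.16,1.79,2.54,
5,GRM,4,1.23,0.42,1.64,2.33,
6,GRM,4,0.88,-1.12,0.73,1.8,
7,GRM,4,0.92,1.75,3.52,4.38,
8,GRM,4,1.36,0.93,2.48,3.61,
9,GRM,4,1.27,0.83,2.48,3.59,
10,GRM,4,1.08,0.6,2.58,3.5,
11,GRM,4,1.17,-0.41,1.47,2.76,
12,GRM,4,1.05,-0.42,1.59,2.92,
13,GRM,4,1.85,0.34,1.46,2.1,
14,GRM,4,1.4,-0.33,1.2,1.95,
15,GRM,4,0.88,0.18,2.13,3.18,
16,GRM,4,1.32,-0.51,1.31,2.36,
17,GRM,4,1.04,0.93,2.75,3.96,
18,GRM,4,1.61,0.51,1.53,2.15,
19,GRM,4,1.64,-0.31,1.38,2.34,
20,GRM,4,1.52,-0.4,1.42,2.53,
21,GRM,4,1.02,0.6,2.55,3.6,
22,GRM,4,1.61,-0.12,1.16,1.93,
23,GRM,4,1.56,0.67,2.13,2.99,
24,GRM,4,1.82,0.14,1.75,2.62,
25,GRM,4,1.63,0.25,1.8,2.86,
26,GRM,4,1.5,-0.55,1.3,2.35,
27,GRM,4,1.18,1.29,2.76,3.95,
28,GRM,4,1.29,0.97,2.29,3.09,
29,GRM,4,1.64,0.15,1.59,2.29,
30,GRM,4,1.45,0.17,1.82,2.65,
31,GRM,4,1.48,0.89,2.45,3.12,
32,GRM,4,1.55,1,2.42,3.21,
33,GRM,4,1.5,1.55,2.75,3.49,
34,GRM,4,1.53,1.08,2.59,3.58,
35,GRM,4,1.52,1.27,2.81,3.81,
36,GRM,4,1.75,1.29,2.57,3.39,
37,GRM,4,1.38,0.24,1.84,2.66,
38,GRM,4,1.31,1.66,3.1,3.84,
39,GRM,3,1.1,-0.01,3.01,,
40,GRM,3,1.46,0.73,3.02,,
41,GRM,3,1.48,0.28,2.15,,
42,GRM,3,1.7,-0.2,1.43,,
43,GRM,3,1.1,-1,1.74,,
44,GRM,3,1.53,0.14,1.84,,
45,GRM,3,0.87,-0.49,2.32,,
46,GRM,3,1.07,1.14,3.43,,
47,GRM,3,1.01,0.79,3.38,,
48,GRM,3,1,1.28,3.5,,
49,GRM,3,0.95,1.3,3.38,,
50,GRM,3,1.39,0.51,2.45,,
51,GRM,3,1.95,0.49,2,,
52,GRM,3,1.92,0.36,2.04,,
53,GRM,3,1.27,0.41,3.01,,
54,GRM,3,1.24,0.93,3.19,,
55,GRM,3,1.58,0.55,1.95,,
56,GRM,3,1.62,0.29,2.03,,
57,GRM,3,1.82,0.05,1.65,,
58,GRM,3,1.37,-0.6,1.8,,
59,GRM,3,1.7,-0.11,1.52,,
60,GRM,5,1.26,-0.6,0.71,2.12,3.02
61,GRM,5,1.32,-0.67,0.36,1.32,2.24
62,GRM,5,1.11,-0.11,1.06,2.27,3.34
63,GRM,5,0.89,0.03,1.6,3.22,4.32
64,GRM,5,1.07,0.18,1.3,2.38,3.04
65,GRM,5,0.97,-0.45,0.58,1.41,2.25
66,GRM,5,1.55,0.14,0.92,1.74,2.29
67,GRM,5,1.38,-0.31,0.7,1.74,2.59
68,GRM,5,1.38,-0.27,0.66,1.65,2.47
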