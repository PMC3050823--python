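day,q0,q25,q50,q75,q100
0,1,1,1,1,1
1,1,1,1,1,1
2,1,1,1,1,1
3,1,1,1,1,1
4,1,1,1,1,1
5,0,0.5,1,1,1
6,0,0.5,1,1,1
7,0,0,0,0.5,1
8,0,0,0,0.5,1
9,0,0,0,0.5,1
10,0,0,0,0.5,1
11,0,0,0,0.5,1
12,0,0,0,0.5,1
13,0,0,0,0.5,1
14,0,0,0,0.5,1
15,0,0,0,0.5,1
16,0,0,0,0.5,1
17,0,0,0,0.5,1
18,0,0,0,0.5,1
19,0,0,0,0.5,1
20,0,0,0,0.5,1
21,0,0,0,0.5,1
22,0,0,0,0.5,1
23,0,0,0,0.5,1
24,0,0,0,0.5,1
25,0,0,0,0.5,1
26,0,0,0,0.5,1
27,0,0,0,0.5,1
28,0,0,0,0.5,1
29,0,0,0,0.5,1
30,0,0,0,0.5,1
31,0,0,0,1,2
32,0,0,0,1,2
33,0,0,0,1,2
34,0,0,0,1,2
35,0,0,0,1,2
36,0,0,0,1,2
37,0,0,0,1,2
38,0,0,0,1,2
39,0,0,0,1,2
40,0,0,0,1,2
41,0,0,0,1,2
42,0,0,0,1.5,3
43,0,0,0,1.5,3
44,0,0,0,1.5,3
45,0,0,0,1.5,3
46,0,0,0,2,4
47,0,0,0,2,4
48,0,0,0,2.5,5
49,0,0,0,2.5,5
50,0,0,0,3,6
51,0,0,0,3,6
52,0,0,0,3,6
53,0,0,0,3,6
54,0,0,0,3,6
55,0,0,0,3.5,7
56,0,0,0,4,8
57,0,0,0,4.5,9
58,0,0,0,4.5,9
59,0,0,0,4.5,9
60,0,0,0,4.5,9
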