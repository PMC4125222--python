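nr,a_y,a_a,f_y,f_a,biologically_relevant
1,0.3,0.7,8,1,0
2,0.3,0.7,9,1,0
3,0.3,0.3,9,2,1
4,0.3,0.3,10,2,1
5,0.3,0.2,10,3,1
6,0.3,0.1,10,6,1
7,0.3,0.1,10,7,1
8,0.4,0.6,7,1,0
9,0.4,0.7,6,1,0
10,0.4,0.3,7,2,1
11,0.5,0.6,5,1,0
12,0.5,0.7,5,1,0
13,0.6,0.6,5,1,0
14,0.6,0.3,5,2,1
15,0.6,0.1,4,7,0
16,0.7,0.6,4,1,0
17,0.7,0.8,3,1,0
18,0.8,0.7,3,1,0
19,1.0,0.1,2,7,0
20,0.3,0.6,11,1,0
21,0.3,0.3,11,2,1
22,0.3,0.1,11,6,1
23,0.2,0.7,12,1,0
24,0.2,0.7,13,1,0
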