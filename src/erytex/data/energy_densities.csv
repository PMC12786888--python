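subject,e1,e2,e3
1,12,14,17
2,14,16,17
3,14,15,16
4,13,15,17
5,13,14,16
6,13,15,17
7,14,16,17
8,12,14,16
9,13,15,16
10,12,14,16
11,12,14,16
12,12,13,15
13,13,15,16
14,12,14,16
15,14,15,16
16,13,15,16
17,12,14,15
18,12,14,15
19,12,14,16
20,12,14,16
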