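pft_index,lai_ref
1,4.0
2,4.5
3,3.5
4,5.0
5,4.5
6,4.0
7,4.0
8,3.5
9,2.0
10,2.0
11,1.5
12,1.0
13,2.0
14,2.5
15,3.0
16,3.5
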