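pft_index,isoprene
1,600.0
2,3000.0
3,1.0
4,7000.0
5,10000.0
6,7000.0
7,10000.0
8,11000.0
9,2000.0
10,4000.0
11,4000.0
12,1600.0
13,800.0
14,200.0
15,1.0
16,1.0
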