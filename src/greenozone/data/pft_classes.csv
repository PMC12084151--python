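pft_index,code,name
1,NET_TEMPERATE,needleleaf evergreen temperate tree
2,NET_BOREAL,needleleaf evergreen boreal tree
3,NDT_BOREAL,needleleaf deciduous boreal tree
4,BET_TROPICAL,broadleaf evergreen tropical tree
5,BET_TEMPERATE,broadleaf evergreen temperate tree
6,BDT_TROPICAL,broadleaf deciduous tropical tree
7,BDT_TEMPERATE,broadleaf deciduous temperate tree
8,BDT_BOREAL,broadleaf deciduous boreal tree
9,BES_TEMPERATE,broadleaf evergreen temperate shrub
10,BDS_TEMPERATE,broadleaf deciduous temperate shrub
11,BDS_BOREAL,broadleaf deciduous boreal shrub
12,C3_GRASS_ARCTIC,arctic C3 grass
13,C3_GRASS_COOL,cool C3 grass
14,C4_GRASS_WARM,warm C4 grass
15,CROP1,crop 1
16,CROP2,crop 2 (corn)
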