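veg_class,phenology,pft_index
tree,evergreen,5
tree,deciduous,7
shrub,,9
grass,,13
crop,,15
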