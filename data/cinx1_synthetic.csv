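population,locus,allele,N,frequency
meadow_east,MSAT1,A,32,0.406
meadow_east,MSAT1,B,32,0.281
meadow_east,MSAT1,C,32,0.219
meadow_east,MSAT1,D,32,0.094
meadow_west,MSAT1,A,34,0.324
meadow_west,MSAT1,B,34,0.353
meadow_west,MSAT1,C,34,0.176
meadow_west,MSAT1,D,34,0.147
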