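taxon,state
Bony_fish_outgroup,0
Chimaeridae,0
Torpedinidae,0
Urotrygonidae,1
Dasyatidae,0
Myliobatidae,0
Squalidae,0
Heterodontidae,0
Ginglymostomatidae,0
Orectolobidae,1
Odontaspididae,0
Scyliorhinidae,1
Triakidae,0
Carcharhinidae,0
Sphyrnidae,0
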