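(Bony_fish_outgroup,(Chimaeridae,((Torpedinidae,(Urotrygonidae,(Dasyatidae,Myliobatidae))),(Squalidae,(Heterodontidae,((Ginglymostomatidae,Orectolobidae),(Odontaspididae,(Scyliorhinidae,(Triakidae,(Carcharhinidae,Sphyrnidae))))))))));
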