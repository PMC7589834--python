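rs_id,substitution,SIFT,PolyPhen2_HumDiv,PolyPhen2_HumVar,MAPP,PANTHER,SNP_GO,PhD_SNP,PredictSNP,PROVEAN,I_Mutant3
rs762112742,S741C,0.05,1,0.996,-,0.663,0.761,0.803,D,-4.265,-1.01
rs1461682152,Y793C,0.05,0.994,0.964,-,0.654,-,0.607,D,-6.46,-0.86
rs985622413,G1050V,0,1,0.999,-,0.568,-,0.733,D,-6.192,-0.58
rs1394779021,S1067C,0,0.999,0.954,-,0.671,-,0.858,D,-3.494,-0.58
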