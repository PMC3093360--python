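rsid,locus,risk_allele_freq,or_per_allele,chromosome_class
rs11249433,1p11.2,0.39,1.16,autosomal
rs1045485,2q33/CASP8,0.85,1.14,autosomal
rs13387042,2q35,0.49,1.12,autosomal
rs4973768,3p24/NEK10-SLC4A7,0.46,1.11,autosomal
rs889312,5q11/MAP3K1,0.28,1.13,autosomal
rs4415084,5p12/MRPS30,0.40,1.19,autosomal
rs2046210,6p12/ESR1,0.36,1.29,autosomal
rs13281615,8q24,0.40,1.08,autosomal
rs1011970,9,0.17,1.09,autosomal
rs2981582,10q26/FGFR2,0.38,1.26,autosomal
rs2380205,10p15,0.43,0.94,autosomal
rs10995190,10q21/ZNF365,0.85,1.16,autosomal
rs704010,10q22,0.39,1.07,autosomal
rs614367,11q13,0.15,1.15,autosomal
rs3817198,11p15/LSP1,0.30,1.07,autosomal
rs999737,14q24/RAD51L1,0.76,1.06,autosomal
rs1244362,16q12/TOX3,0.25,1.20,autosomal
rs6504950,17q/COX11,0.73,1.05,autosomal
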