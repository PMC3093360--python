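rsid,locus,risk_allele_freq,or_per_allele,chromosome_class
rs12621278,2q31/ITGA6,0.94,1.30,autosomal
rs721048,2p15,0.19,1.15,autosomal
rs1465618,2p21/THADA,0.23,1.08,autosomal
rs2660753,3p12,0.11,1.18,autosomal
rs10934853,3q21.3,0.28,1.12,autosomal
rs7679673,4q24/TET2,0.55,1.09,autosomal
rs17021918,4q22/PDLIM5,0.66,1.10,autosomal
rs12500426,4q22/PDLIM6,0.46,1.08,autosomal
rs9364554,6q25,0.29,1.17,autosomal
rs6465657,7q21,0.46,1.12,autosomal
rs10486567,7p15/JAZF1,0.77,1.12,autosomal
rs2928679,8p21,0.42,1.05,autosomal
rs1512268,NKX3.1,0.45,1.18,autosomal
rs620861,8q24,0.61,1.28,autosomal
rs10086908,8q24,0.70,1.25,autosomal
rs445114,8q24,0.64,1.14,autosomal
rs16902094,8q24,0.15,1.21,autosomal
rs6983267,8q24,0.50,1.26,autosomal
rs1447295,8q24,0.10,1.62,autosomal
rs16901979,8q24,0.03,2.10,autosomal
rs4962416,10q26/CTBP2,0.27,1.17,autosomal
rs10993994,10q11/MSMB,0.24,1.25,autosomal
rs7127900,11p15,0.20,1.22,autosomal
rs7931342,11q13,0.51,1.16,autosomal
rs4430796,17q12/HNF1B,0.49,1.24,autosomal
rs11649743,HNF1B,0.80,1.28,autosomal
rs1859962,17q24.3,0.46,1.24,autosomal
rs2735839,19q13/KLK2-KLK3,0.85,1.20,autosomal
rs8102476,19q13.2,0.54,1.12,autosomal
rs5759167,22q13,0.53,1.16,autosomal
rs5945619,Xp11,0.28,1.12,x_linked
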