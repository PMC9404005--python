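id,name,class,log_p,pka,log_d_ref,log_kw_is,log_kw_ip,n_e,a,b
N1,benzyl alcohol,neutral,1.10,NA,1.10,1.32,1.32,0.00,0.39,0.56
N2,"1,4-xylene",neutral,3.15,NA,3.15,3.23,3.23,0.00,0.00,0.16
N3,toluene,neutral,2.73,NA,2.73,2.66,2.66,0.00,0.00,0.14
N4,ethylbenzene,neutral,3.15,NA,3.15,3.20,3.20,0.00,0.00,0.15
N5,anisole,neutral,2.11,NA,2.11,5.60,5.60,0.00,0.00,0.29
N6,benzyl chloride,neutral,5.50,NA,5.50,2.64,2.64,0.00,0.00,0.14
N7,hexamethyl-benzene,neutral,4.61,NA,4.61,4.65,4.65,0.00,0.00,0.12
N8,pentachlorobenzene,neutral,5.18,NA,5.18,4.84,4.84,0.00,0.00,0.00
N9,"1,2-xylene",neutral,3.12,NA,3.12,3.09,3.09,0.00,0.00,0.16
N10,biphenyl,neutral,4.01,NA,4.01,3.75,3.75,0.00,0.00,0.26
N11,phenyl ether,neutral,4.21,NA,4.21,3.73,3.73,0.00,0.00,0.19
N12,naphthalene,neutral,3.30,NA,3.30,3.13,3.13,0.00,0.00,0.20
N13,2-methylnaphthalene,neutral,3.86,NA,3.86,3.65,3.65,0.00,0.00,0.20
N14,"1,3-dichlorobenzene",neutral,3.53,NA,3.53,3.32,3.32,0.00,0.00,0.02
N15,tribromobenzene,neutral,4.51,NA,4.51,4.34,4.34,0.00,0.00,0.00
N16,chlorobenzene,neutral,2.89,NA,2.89,2.72,2.72,0.00,0.00,0.07
N17,bromobenzene,neutral,2.99,NA,2.99,2.84,2.84,0.00,0.00,0.09
N18,benzhydrol,neutral,2.67,NA,2.67,2.86,2.86,0.00,0.41,0.77
N19,pentabromotoluene,neutral,5.87,NA,5.87,5.62,5.62,0.00,0.00,0.00
N20,hexabromobenzene,neutral,6.80,NA,6.80,5.63,5.63,0.00,0.00,0.00
N21,benzaldehyde,neutral,1.47,NA,1.47,1.33,1.33,0.00,0.00,0.39
N22,"1,3-xylene",neutral,3.20,NA,3.20,3.19,3.19,0.00,0.00,0.12
N23,benzene,neutral,2.22,NA,2.22,2.08,2.08,0.00,0.00,0.14
N24,"1,4-diacetoxybenzene",neutral,0.98,NA,0.98,1.45,1.45,0.00,0.00,0.77
N25,"1,4-dibromonaphthalene",neutral,5.02,NA,5.02,4.51,4.51,0.00,0.00,0.16
N26,1-bromonaphthalene,neutral,4.22,NA,4.22,3.77,3.77,0.00,0.00,0.13
W1,benzoic acid,carboxylic_or_phenolic_acid,1.87,4.20,-0.93,0.43,1.68,-1.00,0.59,0.40
W2,2-bromobenzoic acid,carboxylic_or_phenolic_acid,2.20,2.85,-1.95,0.48,1.82,-1.00,0.60,0.43
W3,3-bromobenzoic acid,carboxylic_or_phenolic_acid,2.87,3.81,-0.32,1.46,2.76,-1.00,0.64,0.27
W4,2-chlorobenzoic acid,carboxylic_or_phenolic_acid,2.05,2.94,-2.01,0.55,1.74,-1.00,0.70,0.43
W5,4-chlorobenzoic acid,carboxylic_or_phenolic_acid,2.65,3.98,-0.37,1.34,2.64,-1.00,0.63,0.27
W6,3-methylbenzoic acid,carboxylic_or_phenolic_acid,2.37,4.27,-0.36,1.10,2.21,-1.00,0.60,0.40
W7,"3,5-dimethylbenzoic acid",carboxylic_or_phenolic_acid,2.81,4.30,0.11,1.67,2.69,-1.00,0.59,0.38
W8,phenylacetic acid,carboxylic_or_phenolic_acid,1.41,4.31,-1.28,0.77,1.79,-1.00,0.59,0.61
W9,4-bromophenylacetic acid,carboxylic_or_phenolic_acid,2.31,4.19,-0.50,1.75,2.82,-1.00,0.61,0.56
W10,2-chlorophenylacetic acid,carboxylic_or_phenolic_acid,2.10,4.07,-0.83,1.22,2.25,-1.00,0.61,0.55
W11,2-methylphenylacetic acid,carboxylic_or_phenolic_acid,1.96,4.35,-0.69,1.16,2.15,-1.00,0.60,0.65
W12,2-naphthalenecarboxylic acid,carboxylic_or_phenolic_acid,3.28,4.16,0.44,1.89,2.92,-1.00,0.65,0.46
W13,1-naphthaleneacetic acid,carboxylic_or_phenolic_acid,2.74,4.24,-0.02,1.97,2.98,-1.00,0.60,0.67
W14,2-chlorophenol,carboxylic_or_phenolic_acid,2.15,8.35,2.13,1.95,2.12,-0.03,0.32,0.31
W15,4-bromophenol,carboxylic_or_phenolic_acid,2.59,9.31,2.59,2.37,2.52,0.00,0.67,0.20
W16,"2,6-dibromophenol",carboxylic_or_phenolic_acid,3.36,6.80,2.95,2.30,3.06,-0.55,0.47,0.22
W17,"2,4-dibromophenol",carboxylic_or_phenolic_acid,3.06,7.85,3.00,2.57,3.08,-0.15,0.49,0.27
W18,"2,4,6-trichlorophenol",carboxylic_or_phenolic_acid,3.69,6.21,2.83,2.74,3.73,-0.86,0.42,0.15
W19,"2,4,6-tribromophenol",carboxylic_or_phenolic_acid,4.33,5.95,3.24,3.13,4.26,-0.86,0.42,0.15
W20,pentachlorophenol,carboxylic_or_phenolic_acid,4.69,5.12,2.80,3.82,4.93,-1.00,0.70,0.00
W21,"1,4-benzenedicarboxylic acid",carboxylic_or_phenolic_acid,NA,NA,/,/,1.27,-2.00,1.14,0.77
W22,"1, 3,5-benzenetriol",carboxylic_or_phenolic_acid,NA,NA,/,0.23,0.96,-0.01,1.40,0.82
W23,2-amino-5-nitrophenol,carboxylic_or_phenolic_acid,NA,NA,/,1.15,1.66,-0.04,0.76,0.64
W24,"1,4-benzenediol",carboxylic_or_phenolic_acid,NA,NA,/,0.21,0.60,0.00,1.06,0.57
W25,2-amino-4-nitrophenol,carboxylic_or_phenolic_acid,NA,NA,/,0.74,1.86,-0.04,1.01,0.43
W26,5-nitroisophthalic acid,carboxylic_or_phenolic_acid,NA,NA,/,2.89,2.86,-2.00,1.25,0.87
W27,4-aminobenzoic acid,carboxylic_or_phenolic_acid,NA,NA,/,/,0.45,-0.99,0.80,0.76
W28,2-aminophenol,carboxylic_or_phenolic_acid,NA,NA,/,0.65,0.78,0.00,0.60,0.66
W29,4-hydroxyphenethyl alcohol,carboxylic_or_phenolic_acid,NA,NA,/,1.09,1.06,0.00,0.81,0.67
W30,3-aminophenol,carboxylic_or_phenolic_acid,NA,NA,/,0.33,0.59,0.00,0.65,0.78
W31,ethyl gallate,carboxylic_or_phenolic_acid,NA,NA,/,1.26,2.98,-0.15,1.35,0.93
W32,2-amino-4-tert-butylphenol,carboxylic_or_phenolic_acid,NA,NA,/,2.58,2.68,0.00,0.51,0.59
W33,"3,5-dihydroxybenzoic acid",carboxylic_or_phenolic_acid,NA,NA,/,/,1.01,-1.00,1.56,0.93
S1,benzenesulfonic acid,sulfonic_acid,NA,NA,/,0.30,1.70,-1.00,0.31,0.88
S2,"1,5-naphthalenedisulfonic acid",sulfonic_acid,NA,NA,/,/,2.30,-2.00,0.63,1.71
S3,4-chlorobenzenesulfonic acid,sulfonic_acid,NA,NA,/,1.27,2.57,-1.00,0.31,0.87
S4,4-methylbenzenesulfonic acid,sulfonic_acid,NA,NA,/,1.04,2.11,-1.00,0.31,0.88
S5,5-amino-2-nanphthalenesulfonic acid,sulfonic_acid,NA,NA,/,0.94,2.09,-1.00,0.54,1.26
S6,"2-amino-1,4-benzenedisulfonic acid",sulfonic_acid,NA,NA,/,/,1.75,-2.00,0.85,1.90
S7,1-naphthalenesulfonic acid,sulfonic_acid,NA,NA,/,1.66,2.95,-1.00,0.31,0.94
S8,2-naphthalenesulfonic acid,sulfonic_acid,NA,NA,/,1.65,2.86,-1.00,0.31,0.94
S9,"2,4-dimethylbenzenesulfonic acid",sulfonic_acid,NA,NA,/,1.28,2.64,-1.00,0.31,0.89
S10,4-sulfobenzoic acid,sulfonic_acid,NA,NA,/,/,1.54,-2.00,0.88,1.21
S11,"3,5-dichloro-2-hydroxybenzenesulfonic acid",sulfonic_acid,NA,NA,/,1.95,3.75,-1.14,0.81,0.90
S12,"3,5-dicarbomethoxybenzenesulfonic acid",sulfonic_acid,NA,NA,/,1.63,2.90,-1.00,0.31,1.55
S13,4-hydroxybenzenesulfonic acid,sulfonic_acid,NA,NA,/,/,1.15,-1.01,0.81,1.15
S14,3-sulfobenzoic acid,sulfonic_acid,NA,NA,/,/,1.85,-2.00,0.88,1.21
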