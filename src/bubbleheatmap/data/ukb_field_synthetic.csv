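external_id,variable_id
23400,XXL_VLDL_P
23401,XXL_VLDL_L
23402,XXL_VLDL_PL
23403,XXL_VLDL_C
23404,XXL_VLDL_CE
23405,XXL_VLDL_FC
23406,XXL_VLDL_TG
23407,XXL_VLDL_PL_pct
23408,XXL_VLDL_C_pct
23409,XXL_VLDL_CE_pct
23410,XXL_VLDL_FC_pct
23411,XXL_VLDL_TG_pct
23412,XL_VLDL_P
23413,XL_VLDL_L
23414,XL_VLDL_PL
23415,XL_VLDL_C
23416,XL_VLDL_CE
23417,XL_VLDL_FC
23418,XL_VLDL_TG
23419,XL_VLDL_PL_pct
23420,XL_VLDL_C_pct
23421,XL_VLDL_CE_pct
23422,XL_VLDL_FC_pct
23423,XL_VLDL_TG_pct
23424,L_VLDL_P
23425,L_VLDL_L
23426,L_VLDL_PL
23427,L_VLDL_C
23428,L_VLDL_CE
23429,L_VLDL_FC
23430,L_VLDL_TG
23431,L_VLDL_PL_pct
23432,L_VLDL_C_pct
23433,L_VLDL_CE_pct
23434,L_VLDL_FC_pct
23435,L_VLDL_TG_pct
23436,M_VLDL_P
23437,M_VLDL_L
23438,M_VLDL_PL
23439,M_VLDL_C
23440,M_VLDL_CE
23441,M_VLDL_FC
23442,M_VLDL_TG
23443,M_VLDL_PL_pct
23444,M_VLDL_C_pct
23445,M_VLDL_CE_pct
23446,M_VLDL_FC_pct
23447,M_VLDL_TG_pct
23448,S_VLDL_P
23449,S_VLDL_L
23450,S_VLDL_PL
23451,S_VLDL_C
23452,S_VLDL_CE
23453,S_VLDL_FC
23454,S_VLDL_TG
23455,S_VLDL_PL_pct
23456,S_VLDL_C_pct
23457,S_VLDL_CE_pct
23458,S_VLDL_FC_pct
23459,S_VLDL_TG_pct
23460,XS_VLDL_P
23461,XS_VLDL_L
23462,XS_VLDL_PL
23463,XS_VLDL_C
23464,XS_VLDL_CE
23465,XS_VLDL_FC
23466,XS_VLDL_TG
23467,XS_VLDL_PL_pct
23468,XS_VLDL_C_pct
23469,XS_VLDL_CE_pct
23470,XS_VLDL_FC_pct
23471,XS_VLDL_TG_pct
23472,IDL_P
23473,IDL_L
23474,IDL_PL
23475,IDL_C
23476,IDL_CE
23477,IDL_FC
23478,IDL_TG
23479,IDL_PL_pct
23480,IDL_C_pct
23481,IDL_CE_pct
23482,IDL_FC_pct
23483,IDL_TG_pct
23484,L_LDL_P
23485,L_LDL_L
23486,L_LDL_PL
23487,L_LDL_C
23488,L_LDL_CE
23489,L_LDL_FC
23490,L_LDL_TG
23491,L_LDL_PL_pct
23492,L_LDL_C_pct
23493,L_LDL_CE_pct
23494,L_LDL_FC_pct
23495,L_LDL_TG_pct
23496,M_LDL_P
23497,M_LDL_L
23498,M_LDL_PL
23499,M_LDL_C
23500,M_LDL_CE
23501,M_LDL_FC
23502,M_LDL_TG
23503,M_LDL_PL_pct
23504,M_LDL_C_pct
23505,M_LDL_CE_pct
23506,M_LDL_FC_pct
23507,M_LDL_TG_pct
23508,S_LDL_P
23509,S_LDL_L
23510,S_LDL_PL
23511,S_LDL_C
23512,S_LDL_CE
23513,S_LDL_FC
23514,S_LDL_TG
23515,S_LDL_PL_pct
23516,S_LDL_C_pct
23517,S_LDL_CE_pct
23518,S_LDL_FC_pct
23519,S_LDL_TG_pct
23520,XL_HDL_P
23521,XL_HDL_L
23522,XL_HDL_PL
23523,XL_HDL_C
23524,XL_HDL_CE
23525,XL_HDL_FC
23526,XL_HDL_TG
23527,XL_HDL_PL_pct
23528,XL_HDL_C_pct
23529,XL_HDL_CE_pct
23530,XL_HDL_FC_pct
23531,XL_HDL_TG_pct
23532,L_HDL_P
23533,L_HDL_L
23534,L_HDL_PL
23535,L_HDL_C
23536,L_HDL_CE
23537,L_HDL_FC
23538,L_HDL_TG
23539,L_HDL_PL_pct
23540,L_HDL_C_pct
23541,L_HDL_CE_pct
23542,L_HDL_FC_pct
23543,L_HDL_TG_pct
23544,M_HDL_P
23545,M_HDL_L
23546,M_HDL_PL
23547,M_HDL_C
23548,M_HDL_CE
23549,M_HDL_FC
23550,M_HDL_TG
23551,M_HDL_PL_pct
23552,M_HDL_C_pct
23553,M_HDL_CE_pct
23554,M_HDL_FC_pct
23555,M_HDL_TG_pct
23556,S_HDL_P
23557,S_HDL_L
23558,S_HDL_PL
23559,S_HDL_C
23560,S_HDL_CE
23561,S_HDL_FC
23562,S_HDL_TG
23563,S_HDL_PL_pct
23564,S_HDL_C_pct
23565,S_HDL_CE_pct
23566,S_HDL_FC_pct
23567,S_HDL_TG_pct
23568,Total_P
23569,Total_L
23570,Total_PL
23571,Total_C
23572,Total_CE
23573,Total_FC
23574,Total_TG
23575,VLDL_P
23576,VLDL_L
23577,VLDL_PL
23578,VLDL_C
23579,VLDL_CE
23580,VLDL_FC
23581,VLDL_TG
23582,LDL_P
23583,LDL_L
23584,LDL_PL
23585,LDL_C
23586,LDL_CE
23587,LDL_FC
23588,LDL_TG
23589,HDL_P
23590,HDL_L
23591,HDL_PL
23592,HDL_C
23593,HDL_CE
23594,HDL_FC
23595,HDL_TG
23596,non_HDL_C
23597,Remnant_C
23598,Clinical_LDL_C
23599,HDL2_C
23600,HDL3_C
23601,VLDL_size
23602,LDL_size
23603,HDL_size
23604,ApoA1
23605,ApoB
23606,ApoB_by_ApoA1
23607,Total_FA
23608,DHA
23609,LA
23610,Omega_3
23611,Omega_6
23612,PUFA
23613,MUFA
23614,SFA
23615,Unsaturation
23616,Omega_6_by_Omega_3
23617,DHA_pct
23618,LA_pct
23619,Omega_3_pct
23620,Omega_6_pct
23621,PUFA_pct
23622,MUFA_pct
23623,SFA_pct
23624,PUFA_by_MUFA
23625,Phosphoglyc
23626,TG_by_PG
23627,Cholines
23628,Phosphatidylc
23629,Sphingomyelins
23630,Glucose
23631,Lactate
23632,Pyruvate
23633,Citrate
23634,bOHbutyrate
23635,Acetate
23636,Acetoacetate
23637,Acetone
23638,Albumin
23639,Creatinine
23640,GlycA
23641,Ala
23642,Gln
23643,Gly
23644,His
23645,Total_BCAA
23646,Ile
23647,Leu
23648,Val
23649,Phe
23650,Tyr
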