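reference	transcript	type	percent_identity
AEF30547_1_serine_threonine_protein_kinase_Stpk_V_Dasypyrum_villosum	PCE_F_Chro1G0327700.1	RLK	49.582
ACF33195_1_wheat_kinase_START_domain_protein_Triticum_dicoccoides	PCE_A_Chro3G0212300.2	RLK	39.145
AAM81980_1_barley_stem_rust_resistance_protein_Hordeum_vulgare_subsp_vulgare	PCE_F_Chro3G0201600.2	RLK	37.143
CAB06083_1_Mlo_Hordeum_vulgare_subsp_vulgare	PCE_A_Chro1G0271600.1	RLK	37.770
prf_2207203A_Cf_2_gene	PCE_F_Chro3G0166900.1	RLK	48.116
CAA05268_1_Cf_4_Solanum_habrochaites	PCE_A_Chro4G0181700.1	RLK	32.984
AAC78591_1_disease_resistance_protein_Solanum_lycopersicum_var_cerasiforme	PCE_F_Chro3G0166900.1	RLK	43.860
CAA05274_1_Cf_9_Solanum_pimpinellifolium	PCE_A_Chro1G0477700.1	RLK	34.135
AAK58681_2_verticillium_wilt_disease_resistance_protein_Solanum_lycopersicum	PCE_A_Chro4G0181700.1	RLK	32.176
CAA05269_1_Hcr9_4E_Solanum_habrochaites	PCE_A_Chro1G0477700.1	RLK	35.545
prf_2115395A_Fen_gene	PCE_A_Chro3G0146000.7	RLK	43.110
pir_A49332_disease_resistance_protein_kinase_EC_2_7_1_Pto_tomato	PCE_A_Chro2G0181700.1	RLP	41.237
NP_001233803_1_pto_interacting_protein_1_Solanum_lycopersicum	PCE_F_Chro1G0077800.1	RLK	83.728
AAC49123_1_receptor_kinase_like_protein_Oryza_sativa_Indica_Group	PCE_A_Chro7G0033300.2	RLK	43.837
ABD36512_1_bacterial_blight_resistance_protein_XA26_Oryza_sativa_Indica_Group	PCE_F_Chro1G0236400.1	RLK	40.472
BAE95828_1_chitin_elicitor_binding_protein_partial_Oryza_sativa_Japonica_Group	PCE_F_Chro3G0066900.6	RLP+LysM	27.852
ACR15163_1_B_lectin_receptor_kinase_Oryza_sativa_Indica_Group	PCE_A_Chro4G0044000.3	RLK	35.769
CAE51864_1_RPP27_protein_Arabidopsis_thaliana	PCE_A_Chro4G0181700.1	RLK	30.989
AAY86486_1_RFO1_Arabidopsis_thaliana	PCE_A_Chro4G0180300.3	RLK	44.754
AAG38109_1_protein_serine_threonine_kinase_PBS1_Arabidopsis_thaliana	PCE_F_Chro4G0199100.1	RLK	81.699
AED95370_1_Leucine_rich_receptor_like_protein_kinase_family_protein_Arabidopsis_thaliana	PCE_F_Chro1G0236400.2	RLK	32.598
AEE86224_1_BRI1_associated_receptor_kinase_Arabidopsis_thaliana	PCE_A_Chro4G0170100.2	RLK	49.533
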