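gene_symbol,assay_id,category,is_reference
18S,Hs99999901_s1,endogenous_control,1
RPL32,Hs00851655_g1,endogenous_control,1
BNIP3,Hs00969291_m1,cell_survival_proliferation_differentiation,0
BRCA1,Hs00173233_m1,cell_survival_proliferation_differentiation,0
CCND1,Hs00277039_m1,cell_survival_proliferation_differentiation,0
EPO,Hs01071096_g1,cell_survival_proliferation_differentiation,0
HER2,Hs01001595_m1,cell_survival_proliferation_differentiation,0
IGF2,Hs01005964_g1,cell_survival_proliferation_differentiation,0
NDRG1,Hs00608387_m1,cell_survival_proliferation_differentiation,0
BNIP3L,Hs00188949_m1,cell_survival_proliferation_differentiation,0
TGFB3,Hs00234245_m1,cell_survival_proliferation_differentiation,0
TGM2,Hs00190278_m1,cell_survival_proliferation_differentiation,0
CEBPA,Hs00269972_s1,transcription_factors_feedback,0
CITED2,Hs00366696_m1,transcription_factors_feedback,0
ETS1,Hs00901425_m1,transcription_factors_feedback,0
FOXO3A,Hs00921424_m1,transcription_factors_feedback,0
NR4A1,Hs00374230_m1,transcription_factors_feedback,0
PHD2,Hs00254392_m1,transcription_factors_feedback,0
SNAI1,Hs00195591_m1,transcription_factors_feedback,0
TWIST1,Hs00361186_m1,transcription_factors_feedback,0
VHL,Hs00184451_m1,transcription_factors_feedback,0
PTEN,Hs00829813_s1,transcription_factors_feedback,0
CTSD,Hs00157201_m1,extracellular_matrix_motility,0
CDH1,Hs01023895_m1,extracellular_matrix_motility,0
KRT19,Hs00761767_s1,extracellular_matrix_motility,0
CTGF,Hs01026926_g1,extracellular_matrix_motility,0
CXCR4,Hs00607978_s1,extracellular_matrix_motility,0
MET,Hs01565582_g1,extracellular_matrix_motility,0
MMP2,Hs00234422_m1,extracellular_matrix_motility,0
PLAUR,Hs00182181_m1,extracellular_matrix_motility,0
VIM,Hs00185584_m1,extracellular_matrix_motility,0
GPI,Hs00976711_m1,glucose_metabolism_ph,0
CA9,Hs00154208_m1,glucose_metabolism_ph,0
ENO1,Hs00361415_m1,glucose_metabolism_ph,0
GLUT1,Hs00892681_m1,glucose_metabolism_ph,0
LDHA,Hs00855332_g1,glucose_metabolism_ph,0
NHERF1,Hs00188594_m1,glucose_metabolism_ph,0
PGK1,Hs00943178_g1,glucose_metabolism_ph,0
TPI,Hs01593134_gH,glucose_metabolism_ph,0
COX2,Hs01573471_m1,angiogenesis,0
EDN1,Hs00174961_m1,angiogenesis,0
ENG,Hs00164438_m1,angiogenesis,0
LEP,Hs00174877_m1,angiogenesis,0
VEGF,Hs00900054_m1,angiogenesis,0
AK3,Hs00750261_s1,drug_resistance,0
ABCB1,Hs01067802_m1,drug_resistance,0
ABCG2,Hs01053790_m1,drug_resistance,0
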