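chr1	5000000	5000180	ABL1_ex1
chr1	5003000	5003180	ABL1_ex2
chr1	5006000	5006180	ABL1_ex3
chr1	7000000	7000180	FBXW7_ex1
chr1	7003000	7003180	FBXW7_ex2
chr1	7006000	7006180	FBXW7_ex3
chr1	9000000	9000180	MLH1_ex1
chr1	9003000	9003180	MLH1_ex2
chr1	9006000	9006180	MLH1_ex3
chr1	11000000	11000180	SMARCB1_ex1
chr1	11003000	11003180	SMARCB1_ex2
chr1	11006000	11006180	SMARCB1_ex3
chr1	27022522	27022702	ARID1A_ex1
chr1	27025522	27025702	ARID1A_ex2
chr1	27028522	27028702	ARID1A_ex3
chr2	5137000	5137180	AKT1_ex1
chr2	5140000	5140180	AKT1_ex2
chr2	5143000	5143180	AKT1_ex3
chr2	7137000	7137180	FGFR1_ex1
chr2	7140000	7140180	FGFR1_ex2
chr2	7143000	7143180	FGFR1_ex3
chr2	9137000	9137180	MPL_ex1
chr2	9140000	9140180	MPL_ex2
chr2	9143000	9143180	MPL_ex3
chr2	11137000	11137180	SMO_ex1
chr2	11140000	11140180	SMO_ex2
chr2	11143000	11143180	SMO_ex3
chr2	29415640	29415820	ALK_ex1
chr2	29418640	29418820	ALK_ex2
chr2	29421640	29421820	ALK_ex3
chr3	5274000	5274180	AKT2_ex1
chr3	5277000	5277180	AKT2_ex2
chr3	5280000	5280180	AKT2_ex3
chr3	7274000	7274180	FGFR2_ex1
chr3	7277000	7277180	FGFR2_ex2
chr3	7280000	7280180	FGFR2_ex3
chr3	9274000	9274180	MSH2_ex1
chr3	9277000	9277180	MSH2_ex2
chr3	9280000	9280180	MSH2_ex3
chr3	11274000	11274180	TP53_ex1
chr3	11277000	11277180	TP53_ex2
chr3	11280000	11280180	TP53_ex3
chr4	5411000	5411180	APC_ex1
chr4	5414000	5414180	APC_ex2
chr4	5417000	5417180	APC_ex3
chr4	7411000	7411180	FGFR3_ex1
chr4	7414000	7414180	FGFR3_ex2
chr4	7417000	7417180	FGFR3_ex3
chr4	9411000	9411180	MSH6_ex1
chr4	9414000	9414180	MSH6_ex2
chr4	9417000	9417180	MSH6_ex3
chr4	11411000	11411180	TSC1_ex1
chr4	11414000	11414180	TSC1_ex2
chr4	11417000	11417180	TSC1_ex3
chr5	5548000	5548180	AURKA_ex1
chr5	5551000	5551180	AURKA_ex2
chr5	5554000	5554180	AURKA_ex3
chr5	7548000	7548180	FGFR4_ex1
chr5	7551000	7551180	FGFR4_ex2
chr5	7554000	7554180	FGFR4_ex3
chr5	9548000	9548180	MTOR_ex1
chr5	9551000	9551180	MTOR_ex2
chr5	9554000	9554180	MTOR_ex3
chr5	11548000	11548180	TSC2_ex1
chr5	11551000	11551180	TSC2_ex2
chr5	11554000	11554180	TSC2_ex3
chr6	5685000	5685180	BRAF_ex1
chr6	5688000	5688180	BRAF_ex2
chr6	5691000	5691180	BRAF_ex3
chr6	7685000	7685180	FLT3_ex1
chr6	7688000	7688180	FLT3_ex2
chr6	7691000	7691180	FLT3_ex3
chr6	9685000	9685180	NF1_ex1
chr6	9688000	9688180	NF1_ex2
chr6	9691000	9691180	NF1_ex3
chr6	11685000	11685180	VHL_ex1
chr6	11688000	11688180	VHL_ex2
chr6	11691000	11691180	VHL_ex3
chr6	157099063	157099243	ARID1B_ex1
chr6	157102063	157102243	ARID1B_ex2
chr6	157105063	157105243	ARID1B_ex3
chr7	5822000	5822180	BRCA2_ex1
chr7	5825000	5825180	BRCA2_ex2
chr7	5828000	5828180	BRCA2_ex3
chr7	7822000	7822180	GNA11_ex1
chr7	7825000	7825180	GNA11_ex2
chr7	7828000	7828180	GNA11_ex3
chr7	9822000	9822180	NF2_ex1
chr7	9825000	9825180	NF2_ex2
chr7	9828000	9828180	NF2_ex3
chr7	116312444	116312624	MET_ex1
chr7	116315444	116315624	MET_ex2
chr7	116318444	116318624	MET_ex3
chr8	5959000	5959180	CCND1_ex1
chr8	5962000	5962180	CCND1_ex2
chr8	5965000	5965180	CCND1_ex3
chr8	7959000	7959180	GNAQ_ex1
chr8	7962000	7962180	GNAQ_ex2
chr8	7965000	7965180	GNAQ_ex3
chr8	9959000	9959180	NOTCH1_ex1
chr8	9962000	9962180	NOTCH1_ex2
chr8	9965000	9965180	NOTCH1_ex3
chr9	6096000	6096180	CCNE1_ex1
chr9	6099000	6099180	CCNE1_ex2
chr9	6102000	6102180	CCNE1_ex3
chr9	8096000	8096180	GNAS_ex1
chr9	8099000	8099180	GNAS_ex2
chr9	8102000	8102180	GNAS_ex3
chr9	10096000	10096180	NRAS_ex1
chr9	10099000	10099180	NRAS_ex2
chr9	10102000	10102180	NRAS_ex3
chr9	98205264	98205444	PTCH1_ex1
chr9	98208264	98208444	PTCH1_ex2
chr9	98211264	98211444	PTCH1_ex3
chr10	6233000	6233180	CDK4_ex1
chr10	6236000	6236180	CDK4_ex2
chr10	6239000	6239180	CDK4_ex3
chr10	8233000	8233180	IDH1_ex1
chr10	8236000	8236180	IDH1_ex2
chr10	8239000	8239180	IDH1_ex3
chr10	10233000	10233180	PALB2_ex1
chr10	10236000	10236180	PALB2_ex2
chr10	10239000	10239180	PALB2_ex3
chr11	532242	532422	HRAS_ex1
chr11	535242	535422	HRAS_ex2
chr11	538242	538422	HRAS_ex3
chr11	6370000	6370180	CDK6_ex1
chr11	6373000	6373180	CDK6_ex2
chr11	6376000	6376180	CDK6_ex3
chr11	8370000	8370180	IDH2_ex1
chr11	8373000	8373180	IDH2_ex2
chr11	8376000	8376180	IDH2_ex3
chr11	10370000	10370180	PDGFRA_ex1
chr11	10373000	10373180	PDGFRA_ex2
chr11	10376000	10376180	PDGFRA_ex3
chr11	108093559	108093739	ATM_ex1
chr11	108096559	108096739	ATM_ex2
chr11	108099559	108099739	ATM_ex3
chr12	6507000	6507180	CDKN1B_ex1
chr12	6510000	6510180	CDKN1B_ex2
chr12	6513000	6513180	CDKN1B_ex3
chr12	8507000	8507180	IGF1R_ex1
chr12	8510000	8510180	IGF1R_ex2
chr12	8513000	8513180	IGF1R_ex3
chr12	10507000	10507180	PDGFRB_ex1
chr12	10510000	10510180	PDGFRB_ex2
chr12	10513000	10513180	PDGFRB_ex3
chr13	6644000	6644180	CDKN2A_ex1
chr13	6647000	6647180	CDKN2A_ex2
chr13	6650000	6650180	CDKN2A_ex3
chr13	8644000	8644180	JAK1_ex1
chr13	8647000	8647180	JAK1_ex2
chr13	8650000	8650180	JAK1_ex3
chr13	10644000	10644180	PIK3CA_ex1
chr13	10647000	10647180	PIK3CA_ex2
chr13	10650000	10650180	PIK3CA_ex3
chr14	6781000	6781180	CREBBP_ex1
chr14	6784000	6784180	CREBBP_ex2
chr14	6787000	6787180	CREBBP_ex3
chr14	8781000	8781180	JAK2_ex1
chr14	8784000	8784180	JAK2_ex2
chr14	8787000	8787180	JAK2_ex3
chr14	10781000	10781180	PIK3R1_ex1
chr14	10784000	10784180	PIK3R1_ex2
chr14	10787000	10787180	PIK3R1_ex3
chr15	6918000	6918180	CTNNB1_ex1
chr15	6921000	6921180	CTNNB1_ex2
chr15	6924000	6924180	CTNNB1_ex3
chr15	8918000	8918180	JAK3_ex1
chr15	8921000	8921180	JAK3_ex2
chr15	8924000	8924180	JAK3_ex3
chr15	10918000	10918180	PTEN_ex1
chr15	10921000	10921180	PTEN_ex2
chr15	10924000	10924180	PTEN_ex3
chr16	7055000	7055180	DDR2_ex1
chr16	7058000	7058180	DDR2_ex2
chr16	7061000	7061180	DDR2_ex3
chr16	9055000	9055180	KDR_ex1
chr16	9058000	9058180	KDR_ex2
chr16	9061000	9061180	KDR_ex3
chr16	11055000	11055180	PTPN11_ex1
chr16	11058000	11058180	PTPN11_ex2
chr16	11061000	11061180	PTPN11_ex3
chr17	7192000	7192180	EGFR_ex1
chr17	7195000	7195180	EGFR_ex2
chr17	7198000	7198180	EGFR_ex3
chr17	9192000	9192180	KIT_ex1
chr17	9195000	9195180	KIT_ex2
chr17	9198000	9198180	KIT_ex3
chr17	11192000	11192180	RAF1_ex1
chr17	11195000	11195180	RAF1_ex2
chr17	11198000	11198180	RAF1_ex3
chr17	37844167	37844347	ERBB2_ex1
chr17	37847167	37847347	ERBB2_ex2
chr17	37850167	37850347	ERBB2_ex3
chr17	41196312	41196492	BRCA1_ex1
chr17	41199312	41199492	BRCA1_ex2
chr17	41202312	41202492	BRCA1_ex3
chr18	7329000	7329180	EP300_ex1
chr18	7332000	7332180	EP300_ex2
chr18	7335000	7335180	EP300_ex3
chr18	9329000	9329180	KRAS_ex1
chr18	9332000	9332180	KRAS_ex2
chr18	9335000	9335180	KRAS_ex3
chr18	11329000	11329180	RB1_ex1
chr18	11332000	11332180	RB1_ex2
chr18	11335000	11335180	RB1_ex3
chr19	1205798	1205978	STK11_ex1
chr19	1208798	1208978	STK11_ex2
chr19	1211798	1211978	STK11_ex3
chr19	7466000	7466180	ERBB3_ex1
chr19	7469000	7469180	ERBB3_ex2
chr19	7472000	7472180	ERBB3_ex3
chr19	9466000	9466180	MAP2K1_ex1
chr19	9469000	9469180	MAP2K1_ex2
chr19	9472000	9472180	MAP2K1_ex3
chr19	11466000	11466180	RET_ex1
chr19	11469000	11469180	RET_ex2
chr19	11472000	11472180	RET_ex3
chr20	7603000	7603180	ERBB4_ex1
chr20	7606000	7606180	ERBB4_ex2
chr20	7609000	7609180	ERBB4_ex3
chr20	9603000	9603180	MAP2K2_ex1
chr20	9606000	9606180	MAP2K2_ex2
chr20	9609000	9609180	MAP2K2_ex3
chr20	11603000	11603180	ROS1_ex1
chr20	11606000	11606180	ROS1_ex2
chr20	11609000	11609180	ROS1_ex3
chr21	7740000	7740180	ESR1_ex1
chr21	7743000	7743180	ESR1_ex2
chr21	7746000	7746180	ESR1_ex3
chr21	9740000	9740180	MDM2_ex1
chr21	9743000	9743180	MDM2_ex2
chr21	9746000	9746180	MDM2_ex3
chr21	11740000	11740180	SMAD4_ex1
chr21	11743000	11743180	SMAD4_ex2
chr21	11746000	11746180	SMAD4_ex3
chr22	7877000	7877180	EZH2_ex1
chr22	7880000	7880180	EZH2_ex2
chr22	7883000	7883180	EZH2_ex3
chr22	9877000	9877180	MDM4_ex1
chr22	9880000	9880180	MDM4_ex2
chr22	9883000	9883180	MDM4_ex3
chr22	11877000	11877180	SMARCA4_ex1
chr22	11880000	11880180	SMARCA4_ex2
chr22	11883000	11883180	SMARCA4_ex3
chrX	76760356	76760536	ATRX_ex1
chrX	76763356	76763536	ATRX_ex2
chrX	76766356	76766536	ATRX_ex3
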