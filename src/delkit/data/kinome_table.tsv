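systematic_id	name	group_path	deletion_status	phenotypes	is_ffk
AN4238	SchA	AGC/Akt	viable		0
AN5973	PkcB	AGC/Akt	lethal	microcolony	0
AN5529	CotA	AGC/NDR	lethal	microcolony,brown_pigment,polarity_defect	0
AN10485	An-Stk21	AGC/NDR	viable		0
AN7572	SrrB	AGC/NDR	viable	NaCl_sensitive	0
AN8751	SidB	AGC/NDR	viable	strong_growth_defect,septation_conidiation_defect,NaCl_sensitive	0
AN3110	An-Ksg1	AGC/PDK1	lethal	microcolony	0
AN4717	PkaB	AGC/PKA	viable		0
AN6305	PkaA	AGC/PKA	viable	strong_growth_defect,sucrose_remediated,NaCl_remediated	0
AN0106	PkcA	AGC/PKC/PKC	lethal	swollen	0
AN4980	An-Psk1	AGC/RSK	viable		0
AN0144	An-Nrc2	AGC/RSK	viable	moderate_growth_defect	0
AN7537	An-Ppk33	AGC/YANK	viable	NaCl_sensitive	0
AN2412	CmkA	CAMK/CAMK1	viable	moderate_growth_defect,increased_pigment	0
AN3065	CmkB	CAMK/CAMK1	viable		0
AN4483	CmkD	CAMK/CAMK1	viable		0
AN7695	An-Snf1	CAMK/CAMKL/AMPK	viable		0
AN5494	ChkA	CAMK/CAMKL/CHK1	viable	HU_sensitive,DEO_sensitive	0
AN11101	An-Gin4	CAMK/CAMKL/GIN4	viable	early_sexual_development	0
AN1171	An-Kin1	CAMK/CAMKL/Kin1	viable	moderate_growth_defect	0
AN0822	KfsA	CAMK/CAMKL/Kin4	viable	moderate_growth_defect	0
AN5759	An-Stk19	CAMK/CAMKL/MARK	viable		0
AN4536	An-Psk1	CAMK/CAMKL/PASK	viable		0
AN6347	An-Stk26	CAMK/CAMK-Unique	viable		0
AN7737	An-Mek1	CAMK/CAMK-Unique	viable		0
AN1097	An-Nnk1	CAMK/CAMK-Unique	viable		0
AN4279	ChkB	CAMK/RAD53	viable	HU_sensitive	0
AN7563	ChkC	CAMK/RAD53	viable	HU_sensitive	0
AN4563	CkiA	CK1/CK1/CK1-D	lethal	short_germling_arrest	0
AN5757	CkiB	CK1/CK1/CK1-G	viable	strong_growth_defect	0
AN0699	An-Cak1	CMGC/CDK/CDC2	viable	strong_growth_defect,heterokaryons_recovered	0
AN4182	NimX	CMGC/CDK/CDC2	lethal	cell_cycle	0
AN1867	PhoB	CMGC/CDK/CDK5	viable		0
AN8261	PhoA	CMGC/CDK/CDK5	viable	NaCl_sensitive	0
AN8285	An-Cdk7	CMGC/CDK/CDK7	lethal	swollen,enlarged_vacuoles	0
AN2489	An-Ssn3	CMGC/CDK/CDK8	viable	moderate_growth_defect	0
AN8865	PtkA	CMGC/CDK	viable	strong_growth_defect,NaCl_sensitive	0
AN8190	An-Stk47	CMGC/CDK/CRK7	viable	strong_growth_defect,NaCl_sensitive	0
AN6044	NpkA	CMGC/CDK	viable		0
AN1485	An-Cka1	CMGC/CK2	lethal	microcolony	0
AN0988	An-Lkh1	CMGC/CLK	viable	strong_growth_defect	0
AN4936	An-Prp4	CMGC/DYRK/PRP4	lethal	short_germling_arrest,swollen	0
AN7104	An-Yak1	CMGC/DYRK/YAK	viable	moderate_growth_defect,yellow_pigment	0
AN7678	An-Pom1	CMGC/DYRK/YAK	viable		0
AN6508	An-Gsk3	CMGC/GSK	viable	strong_growth_defect,brown_pigment,conidiation_defect,sucrose_remediated	0
AN1017	HogA	CMGC/MAPK/ERK	viable	NaCl_sensitive	0
AN3719	MpkB	CMGC/MAPK/ERK	viable	moderate_growth_defect,arrested_sexual_development	0
AN4668	MpkC	CMGC/MAPK/ERK	viable		0
AN5666	MpkA	CMGC/MAPK/ERK	viable	branched_germling_arrest,NaCl_remediated,sucrose_remediated	0
AN6243	ImeB	CMGC/RCK/MAK	viable	moderate_growth_defect	0
AN7185	SrpkA	CMGC/SRPK	viable	moderate_growth_defect,NaCl_sensitive	0
AN10895	SrpkB	CMGC/SRPK	viable		0
AN1315	SrpkC	CMGC/SRPK	viable		0
AN10325	SrpkD	CMGC/SRPK	viable		0
AN10937	SrpkE	CMGC/SRPK	viable		0
AN10082	SrpkF	CMGC/SRPK	viable		0
AN10462	SrpkG	CMGC/SRPK	viable		0
AN5815	An-Aurora	Other/Aur	lethal	nulls_not_generated	0
AN3946	SldA	Other/BUB	viable	moderate_growth_defect,benomyl_sensitive,NaCl_sensitive,colony_color	0
AN5728	An-Stk22	Other/CAMKK/ELM	viable		0
AN8827	CmkC	Other/CAMKK/ELM	viable	NaCl_sensitive	0
AN3450	An-Cdc7	Other/CDC7	lethal	cell_cycle,swollen	0
AN10019	An-Oca2	Other/HAL	viable		0
AN2943	RfeA	Other/HAL	viable		0
AN8830	HalA	Other/HAL	viable	moderate_growth_defect,NaCl_sensitive	0
AN2054	An-Haspin	Other/Haspin	viable		0
AN1665	An-Stk51	Other/IKS	viable		0
AN0235	IreA	Other/IRE	lethal	swollen	0
AN10515	An-Prk1	Other/NAK/NAK	viable	strong_growth_defect	0
AN10193	An-Env7	Other/NAK	viable		0
AN9504	NimA	Other/NEK/NEK2	lethal	cell_cycle	0
AN2246	An-Gcn2	Other/PEK/GCN2	viable		0
AN7321	An-HriA	Other/PEK/HRI	viable		0
AN1560	PlkA	Other/PLK	viable	strong_growth_defect,early_sexual_development,NaCl_sensitive	0
AN2265	An-Ksp1	Other/RAN	viable		0
AN4935	An-Ran1	Other/RAN	viable		0
AN4322	An-Scy1	Other/SCY1	viable		0
AN2927	An-Mps1	Other/TTK	lethal	nulls_not_generated	0
AN1632	An-Atg1	Other/ULK/ULK	viable		0
AN0576	An-Vps15	Other/VPS15	lethal	microcolony	0
AN3001	An-Isr1	Other/Other-Unique	viable		0
AN5822	An-Wee1	Other/WEE	lethal	cell_cycle	0
AN4385	SepH	STE/STE11/CDC15	lethal	strong_growth_defect,septation_conidiation_defect,NaCl_sensitive,heterokaryons_recovered	0
AN10153	SskB	STE/STE11/STE11	viable	NaCl_sensitive,sucrose_sensitive	0
AN2269	SteC	STE/STE11	viable	moderate_growth_defect,arrested_sexual_development	0
AN4887	BckA	STE/STE11	lethal	branched_germling_arrest,NaCl_remediated,sucrose_remediated	0
AN6339	An-Pod6	STE/STE20	lethal	microcolony,brown_pigment,polarity_defect	0
AN2067	An-Ste20	STE/STE20/PAKA	viable	increased_pigment	0
AN8836	An-Cla4	STE/STE20/PAKA	viable	strong_growth_defect	0
AN11032	SepL	STE/STE20/YSK	viable	strong_growth_defect,septation_conidiation_defect,NaCl_sensitive	0
AN5674	An-Mst1	STE/STE20/YSK	viable	early_sexual_development,incomplete_sexual_development	0
AN0931	PbsA	STE/STE7/STE7	viable	NaCl_sensitive,sucrose_sensitive	0
AN3422	Ste7	STE/STE7	viable	moderate_growth_defect,arrested_sexual_development	0
AN4189	MkkA	STE/STE7	lethal	branched_germling_arrest,NaCl_remediated,sucrose_remediated	0
AN7986	FfkA	Unclassified/Ank	viable		1
AN10819	FfkB	Unclassified/Ank	viable		1
AN2373	FfkC	Unclassified/Ank	viable		1
AN1789	FfkD	Unclassified	viable		1
AN10869	FfkE	Unclassified	viable		1
AN4196	FfkF	Unclassified	viable		1
AN6192	FfkG	Unclassified	viable		1
AN5511	FfkH	Unclassified	viable		1
AN6768	FfkI	Unclassified	viable		1
AN6758	FfkJ	Unclassified	not_determined		1
AN9302	FfkK	Unclassified	not_determined		1
AN10800	PkpA	Atypical/PDHK	viable		0
AN9461	PkpB	Atypical/PDHK	not_determined		0
AN6207	PkpC	Atypical/PDHK	viable		0
AN4278	An-Stt4	Atypical/PIKK	lethal_kinase_domain	microcolony,variable_phenotype,cell_cycle	0
AN4709	An-Vps34	Atypical/PIKK	lethal	microcolony	0
AN10791	An-Lsb6	Atypical/PIKK	viable	strong_growth_defect,heterokaryons_recovered	0
AN0038	AtmA	Atypical/PIKK/ATM	viable	camptothecin_sensitive	0
AN6975	UvsB	Atypical/PIKK/ATR	viable	moderate_growth_defect,HU_sensitive,DEO_sensitive,camptothecin_sensitive,colony_color	0
AN5982	TorA	Atypical/PIKK/FRAP	lethal	short_germling_arrest,early_septation	0
AN6363	SudD	Atypical/RIO/RIO1	lethal	short_germling_arrest,swollen	0
AN0124	An-Rio2	Atypical/RIO/RIO2	lethal	short_germling_arrest	0
AN5296	TcsA	Atypical/HisK	viable		0
AN1800	TcsB	Atypical/HisK	viable		0
AN7945	hk-2	Atypical/HisK	viable		0
AN2581	hk-8-1	Atypical/HisK	viable		0
AN4113	hk-8-2	Atypical/HisK	viable		0
AN6820	hk-8-3	Atypical/HisK	viable		0
AN4818	hk-8-4	Atypical/HisK	viable		0
AN3214	hk-8-5	Atypical/HisK	viable		0
AN2363	hk-8-6	Atypical/HisK	viable		0
AN9048	hk-8-7	Atypical/HisK	viable		0
AN4447	hk-9	Atypical/HisK	viable		0
AN4479	NikA	Atypical/HisK	viable	strong_growth_defect	0
AN3102	PhkA	Atypical/HisK	viable_kinase_domain		0
AN3101	PhkB	Atypical/HisK	viable		0
AN9008	FphA	Atypical/HisK	viable		0
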