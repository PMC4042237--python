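kind	sequence	genes	n_xtandem	n_omssa	digestion_class
fusion	EQISENPTEATDIDFIR	PTPN12:HSP90AA1	5	9	A
fusion	VIFMDGNGYISAAELR	HN1:CALM1	9	3	A
fusion	IMGIPEEEQMVLSR	MYH9:ALK	4	5	A
fusion	ENVGLEEEQQALQK	PDIA6:TPM2	3	6	A
fusion	AVFVDLEPTVIGGGSVR	TUBA1C:PCGF2	5	3	A
fusion	AAEDDEFTHLYTLIVRPDNTYEVK	GPR115:CALR	2	5	A
fusion	EDSELLISSWLVTDR	DOCK9:BAZ1A	3	2	A
fusion	AVQQELDDLLVDLDHQR	TGFBI:MYH9	2	2	A
fusion	QVTNFLSSINEEITPR	FGFR1:BCR	1	2	A
fusion	ERPAPGQAVLSGGTTMYPGIADR	ACO2:ACTB	1	2	A
fusion	LSAASTWLEDEGVGATTVLFK	HYOU1:HMGA1	1	1	A
fusion	AVFVDLEPTVIEPVR	TUBA1A:PTPN13	1	1	A
fusion	EAREVIELTK	CLCN3:SMNDC1	4	5	B
fusion	NKAEILELAGNAAR	ATP2B4:H2AFY	3	3	B
fusion	EAKGESGPSGPAGPTGAR	USP6:COL1A1	3	2	B
fusion	GRTGDAGPVGEAGAAGPAGPAGPR	COL1A1:COL1A2	1	2	B
fusion	AKQEPEVNGGSGDAVPSGNEVSENMEEEEEALSLMK	NASP:WIPF1	1	2	B
fusion	AHSEEPMEIFVDDETK	ESPN:BAT1	4	6	C
fusion	TTGIVMDSGDGVTHTVPDASRVP	ACTB:GNAS	1	1	C
splicing	INGGGGGSVPGIER	HNRNPM	12	0	A
splicing	GDVEEDETIPDSPSVLETIR	TNPO1	2	6	A
splicing	GGSGYGDLGGPIITTQVTIPK	HNRNPK	3	3	A
splicing	RVEDEVNSGVGQDGSLLSSPFLK	SLC35A4	2	2	B
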