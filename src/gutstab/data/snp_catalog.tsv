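SNP_ID	Genome_pos	Mut_type	Mut_base	Mut_pro	Ref_Gene	Product	COG_categories	KO_No.	Pathway_No.
SNP01	1375280	Non-syn	C-T	R61C	LBP_RS06445	Membrane protein	-	-	-
SNP02	1059218	Non-syn	G-A	G598S	LBP_RS04920	Phosphatidic acid phosphatase	COG0671[I]	K19302	Metabolism[PATH:ko00550]
SNP03	1760063	Nonsense	C-T	Q808X	LBP_RS08305	Epimerase	COG1087[M]	K01784	Metabolism[PATH:ko00052,ko00520]
SNP04	2090448	Non-syn	G-T	D358Y	LBP_RS10060	Hypothetical protein	-	-	-
SNP05	1441158	Syn	G-T	V474V	LBP_RS06740	Phosphohydrolase	-	-	-
SNP06	710832	Non-syn	A-G	S160G	LBP_RS03240	Bifunctional amino acid aminotransferase/2-hydroxyacid dehydrogenase	COG1052[CHR]	K03778	Metabolism[PATH:ko00620]
SNP07	1859386	Nonsense	G-T	E574X	LBP_RS08745	23S rRNA methyltransferase	COG0500[QR]	K00563	-
SNP08	3005584	Syn	A-G	P1509P	LBP_RS14195	Hypothetical protein	-	-	-
SNP09	2188536	Syn	T-G	G744G	LBP_RS10480	1-deoxy-D-xylulose-5-phosphate synthase	COG1154[HI]	K01662	Metabolism[PATH:ko00730,ko00900]
SNP10	2228459	Syn	C-T	Y81Y	LBP_RS10685	Ribonucleotide reductase assembly protein NrdI	COG1780[F]	K03647	-
SNP11	2253167	Non-syn	C-A	P601T	LBP_RS10775	Orotidine 5'-phosphate decarboxylase	COG0284[F]	K01591	Metabolism[PATH:ko00240]
SNP12	1929398	Syn	C-T	T2319T	LBP_RS09215	Hypothetical protein	-	-	-
SNP13	2570686	Non-syn	G-A	D1942N	LBP_RS12200	Cell wall anchor protein	-	-	-
SNP14	2196065	Syn	C-A	V1275V	LBP_RS10515	Oligoendopeptidase	COG1164[E]	-	-
SNP15	608137	Non-syn	A-G	T2746A	LBP_RS02810	Excinuclease ABC subunit A	COG0178[L]	K03701	Genetic Information Processing[PATH:ko03420]
SNP16	2076616	Intergenic	T-C	-	-	-	-	-	-
SNP17	879878	Syn	T-C	G693G	LBP_RS04100	ABC transporter permease	COG0619[P]	K16785	Environmental Information Processing[PATH:ko02010]
SNP18	928900	Non-syn	C-T	T707I	LBP_RS04305	Thiol reductant ABC exporter subunit CydD	COG4988[CO]	K16013	Environmental Information Processing[PATH:ko02010]
SNP19	1800964	Non-syn	G-A	M99I	LBP_RS08475	GTP-binding protein	COG1217[T]	K06207	-
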