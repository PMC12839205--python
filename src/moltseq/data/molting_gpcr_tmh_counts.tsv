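# Per-tool transmembrane-helix counts for candidate GPCR proteins of the
# E. sinensis molting-cycle study, one row per (comparison, protein, tool).
# SWISS-MODEL homo-dimer models use the per-chain syntax (e.g. 7x2).
comparison	protein_id	gene_name	tool	count
Mu_A_vs_Mu_C	evm.TU.CM024127.1.244	FMRFaR	TMHMM	6
Mu_A_vs_Mu_C	evm.TU.CM024127.1.244	FMRFaR	PSIPRED	7
Mu_A_vs_Mu_C	evm.TU.CM024127.1.244	FMRFaR	SWISS-MODEL	7
Mu_A_vs_Mu_C	evm.TU.CM024146.1.116	GRM7	TMHMM	7
Mu_A_vs_Mu_C	evm.TU.CM024146.1.116	GRM7	PSIPRED	7
Mu_A_vs_Mu_C	evm.TU.CM024146.1.116	GRM7	SWISS-MODEL	7x2
Mu_A_vs_Mu_C	evm.TU.CM024164.1.176	gpr161	TMHMM	7
Mu_A_vs_Mu_C	evm.TU.CM024164.1.176	gpr161	PSIPRED	7
Mu_A_vs_Mu_C	evm.TU.CM024164.1.176	gpr161	SWISS-MODEL	7
Mu_A_vs_Mu_C	evm.TU.CM024134.1.314	mth2	TMHMM	7
Mu_A_vs_Mu_C	evm.TU.CM024134.1.314	mth2	PSIPRED	7
Mu_A_vs_Mu_C	evm.TU.CM024134.1.314	mth2	SWISS-MODEL	7
Mu_A_vs_Mu_C	evm.TU.CM024100.1.415	moody	TMHMM	7
Mu_A_vs_Mu_C	evm.TU.CM024100.1.415	moody	PSIPRED	7
Mu_A_vs_Mu_C	evm.TU.CM024100.1.415	moody	SWISS-MODEL	7
Mu_D_vs_Mu_E	evm.TU.CM024164.1.176	gpr161	TMHMM	7
Mu_D_vs_Mu_E	evm.TU.CM024164.1.176	gpr161	PSIPRED	7
Mu_D_vs_Mu_E	evm.TU.CM024164.1.176	gpr161	SWISS-MODEL	7
Mu_D_vs_Mu_E	evm.TU.CM024137.1.63	Kpna6	TMHMM	7
Mu_D_vs_Mu_E	evm.TU.CM024137.1.63	Kpna6	PSIPRED	7
Mu_D_vs_Mu_E	evm.TU.CM024137.1.63	Kpna6	SWISS-MODEL	7
Mu_D_vs_Mu_E	evm.TU.CM024165.1.210	ADRB2	TMHMM	8
Mu_D_vs_Mu_E	evm.TU.CM024165.1.210	ADRB2	PSIPRED	7
Mu_D_vs_Mu_E	evm.TU.CM024165.1.210	ADRB2	SWISS-MODEL	7
Mu_D_vs_Mu_E	evm.TU.CM024127.1.244	FMRFaR	TMHMM	6
Mu_D_vs_Mu_E	evm.TU.CM024127.1.244	FMRFaR	PSIPRED	7
Mu_D_vs_Mu_E	evm.TU.CM024127.1.244	FMRFaR	SWISS-MODEL	7
Mu_D_vs_Mu_E	evm.TU.CM024152.1.288	SSTR2	TMHMM	7
Mu_D_vs_Mu_E	evm.TU.CM024152.1.288	SSTR2	PSIPRED	7
Mu_D_vs_Mu_E	evm.TU.CM024152.1.288	SSTR2	SWISS-MODEL	7
Mu_D_vs_Mu_E	evm.TU.CM024144.1.276	rhodopsin-like	TMHMM	1
Mu_D_vs_Mu_E	evm.TU.CM024144.1.276	rhodopsin-like	PSIPRED	1
Mu_D_vs_Mu_E	evm.TU.CM024144.1.276	rhodopsin-like	SWISS-MODEL	2
Mu_D_vs_Mu_E	evm.TU.CM024104.1.157	HTR4	TMHMM	6
Mu_D_vs_Mu_E	evm.TU.CM024104.1.157	HTR4	PSIPRED	6
Mu_D_vs_Mu_E	evm.TU.CM024104.1.157	HTR4	SWISS-MODEL	7
Mu_E_vs_Mu_A	evm.TU.CM024134.1.314	mth2	TMHMM	7
Mu_E_vs_Mu_A	evm.TU.CM024134.1.314	mth2	PSIPRED	7
Mu_E_vs_Mu_A	evm.TU.CM024134.1.314	mth2	SWISS-MODEL	7
Mu_E_vs_Mu_A	evm.TU.CM024136.1.65_evm.TU.CM024136.1.66	sky	TMHMM	0
Mu_E_vs_Mu_A	evm.TU.CM024136.1.65_evm.TU.CM024136.1.66	sky	PSIPRED	2
Mu_E_vs_Mu_A	evm.TU.CM024136.1.65_evm.TU.CM024136.1.66	sky	SWISS-MODEL	7
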