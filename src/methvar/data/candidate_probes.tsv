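probe_id	gene	q_fdr
cg18796523	ALG11;ATP7B	8.46e-04
cg04087237	CACNB4	4.41e-02
chr16:50203861		9.91e-03
cg13303475	NT5DC3	1.10e-02
cg01918706	UBE2T	4.37e-02
cg01657694	KLHL22	3.09e-02
cg13694867	SIM2	2.54e-02
cg05168033	EFEMP1	1.24e-03
cg26952925	ADCY9	1.16e-02
cg13562542	GPR27;EIF4E3	5.93e-03
cg17364044	PELI1	3.10e-02
cg26447413	GAS1	2.02e-02
cg11265160	TMEM132C	1.48e-02
cg21849932	LIME1	1.87e-02
cg04364540	FAM160B1	4.27e-03
cg14099514	PLCXD3	1.02e-02
cg19176559		3.46e-03
cg19041132	SPHK1	6.22e-07
cg12053442		2.85e-02
cg01558909	HBM	1.85e-05
cg14993491	PCSK9	4.54e-03
cg13408519		3.24e-06
cg12604181	CTSH	1.04e-09
cg18404925	RAC1	1.50e-07
cg13978347	ASTN2	1.08e-04
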