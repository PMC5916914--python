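probe_id	IC01.001	IC01.010	IC01.037	IC01.048	IC01.055	IC01.063	IC01.098	IC01.105	IC01.119	IC01.151	IC01.153	IC01.178	IC05.001	IC25.001
cg18796523	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
cg04087237	0.00	0.00	0.00	0.00	0.01	0.00	0.00	0.00	0.00	0.00	0.01	0.00	0.00	0.00
chr16:50203861	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	-0.01	-0.01
cg13303475	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.01	0.00	0.00	0.00	0.00	-0.01	0.00
cg01918706	0.00	0.00	0.00	0.00	0.00	0.00	0.01	0.01	0.00	0.00	0.00	0.00	-0.01	0.01
cg01657694	0.00	0.01	0.00	0.00	-0.01	0.00	0.00	0.00	0.00	0.00	0.01	0.00	-0.01	0.00
cg13694867	0.00	-0.01	0.00	0.00	0.00	0.00	0.00	0.01	0.01	0.01	0.00	0.00	0.00	0.00
cg05168033	0.00	0.00	0.00	0.00	0.00	0.00	-0.01	0.00	0.00	0.00	0.00	0.00	-0.01	0.00
cg26952925	0.00	-0.01	0.01	0.00	0.00	0.00	0.01	0.00	0.00	0.00	-0.01	0.00	0.00	0.01
cg13562542	0.01	0.00	0.00	0.00	-0.01	0.00	0.00	0.01	0.00	0.00	0.00	0.00	0.00	0.00
cg17364044	-0.01	0.01	-0.01	0.00	0.01	0.00	-0.01	0.00	0.00	0.01	-0.01	0.00	0.00	0.00
cg26447413	0.00	-0.01	-0.01	0.01	0.00	0.00	-0.01	0.00	0.00	0.01	0.00	0.00	0.00	0.00
cg11265160	0.00	-0.01	-0.01	0.01	-0.01	0.00	0.00	0.02	0.00	0.00	0.00	0.00	0.00	-0.01
cg21849932	0.00	0.00	0.00	0.00	0.00	0.00	0.03	0.00	-0.01	0.01	0.00	0.00	-0.01	0.01
cg04364540	-0.01	0.00	0.01	0.00	0.02	0.01	0.00	0.00	0.01	0.00	0.01	-0.01	-0.01	-0.01
cg14099514	0.00	0.00	-0.01	0.00	-0.01	0.00	-0.01	-0.02	0.00	0.00	-0.02	0.02	0.00	0.01
cg19176559	-0.01	-0.01	0.01	0.00	-0.02	0.01	-0.01	-0.01	0.01	0.01	0.01	-0.01	0.00	0.01
cg19041132	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.01	0.00	0.00	0.00	0.00	0.00	0.00
cg12053442	-0.01	0.00	-0.01	0.02	0.01	0.01	-0.03	0.00	-0.01	0.02	-0.01	0.00	0.01	-0.01
cg01558909	0.00	-0.01	-0.01	0.00	0.01	0.01	-0.01	0.03	0.01	0.02	-0.01	0.01	0.00	-0.01
cg14993491	-0.02	0.01	0.02	-0.02	0.01	0.02	-0.03	-0.01	0.05	0.03	-0.04	-0.02	0.02	-0.02
cg13408519	0.02	0.00	-0.01	0.02	0.00	0.02	0.00	-0.02	-0.01	0.02	0.01	0.00	-0.01	-0.01
cg12604181	0.00	0.01	0.00	0.00	0.01	0.00	0.00	0.02	0.00	0.00	0.01	0.00	0.00	-0.01
cg18404925	0.00	0.00	-0.01	-0.01	0.01	0.01	-0.02	0.00	0.01	-0.03	0.01	0.00	-0.01	-0.03
cg13978347	-0.01	-0.03	0.00	0.06	-0.02	0.02	0.01	0.00	0.03	0.01	0.06	-0.04	0.00	0.00
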