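probe_id	IC01.001	IC01.010	IC01.037	IC01.048	IC01.055	IC01.063	IC01.098	IC01.105	IC01.119	IC01.151	IC01.153	IC01.178	IC05.001	IC25.001
cg18796523	0.00	0.00	0.01	0.00	0.00	0.00	0.00	0.02	-0.01	0.03	0.01	0.00	0.00	0.00
cg04087237	0.04	0.02	0.00	-0.01	0.00	0.00	-0.01	0.01	0.00	0.00	0.00	0.00	0.00	-0.01
chr16:50203861	0.00	-0.01	0.00	-0.01	0.01	0.00	0.00	0.00	0.00	0.06	0.00	0.01	0.00	0.00
cg13303475	0.00	0.00	0.00	0.00	0.01	-0.01	-0.01	0.00	0.00	0.00	0.00	0.06	-0.01	0.00
cg01918706	0.00	0.00	0.01	0.00	0.00	0.00	0.06	0.00	0.00	0.00	0.01	0.00	0.00	-0.01
cg01657694	0.03	0.01	0.00	0.01	0.00	0.00	0.00	0.06	0.00	0.00	0.00	0.01	-0.01	-0.01
cg13694867	0.02	0.00	-0.01	0.01	-0.01	-0.02	0.00	0.00	-0.03	-0.01	0.00	-0.01	0.00	0.05
cg05168033	0.04	0.01	0.00	0.00	0.00	-0.01	-0.01	0.01	0.00	0.01	0.00	0.01	0.00	0.06
cg26952925	0.00	0.00	0.00	0.01	0.00	-0.01	0.00	0.01	0.00	0.01	0.00	-0.01	0.00	0.08
cg13562542	0.07	0.00	-0.02	0.01	0.00	0.00	-0.01	-0.01	0.01	0.00	0.00	0.01	-0.01	0.01
cg17364044	0.00	-0.02	-0.01	-0.01	-0.02	0.00	0.00	0.10	0.00	0.01	0.01	-0.01	-0.01	0.00
cg26447413	-0.01	0.01	0.00	0.01	-0.02	-0.01	-0.01	-0.02	0.01	0.10	-0.01	0.00	0.02	0.00
cg11265160	0.01	0.08	0.00	0.01	-0.02	-0.05	-0.04	-0.01	0.00	0.00	-0.06	0.00	0.01	0.00
cg21849932	-0.01	0.01	0.00	0.00	0.00	0.01	0.13	0.00	0.00	0.00	0.00	0.00	-0.01	0.00
cg04364540	0.00	-0.01	-0.01	0.00	0.01	0.00	0.00	0.01	-0.01	0.00	0.00	0.15	-0.02	0.00
cg14099514	0.02	0.03	-0.01	0.00	-0.02	-0.04	-0.01	0.00	-0.01	0.14	-0.03	0.02	0.00	0.00
cg19176559	0.04	-0.03	0.00	0.00	-0.01	-0.02	0.15	0.01	0.00	0.01	-0.02	0.01	0.00	0.02
cg19041132	0.00	0.00	0.00	0.02	0.12	-0.01	0.00	0.01	0.00	0.00	-0.01	0.13	-0.01	0.00
cg12053442	-0.01	-0.01	0.01	-0.01	0.00	0.00	-0.01	-0.15	0.01	0.00	0.02	0.00	0.01	-0.11
cg01558909	0.20	0.00	-0.01	-0.01	0.01	0.29	0.07	0.00	-0.02	0.03	0.01	0.00	-0.01	0.00
cg14993491	-0.04	0.25	0.02	-0.05	-0.04	0.36	-0.05	-0.02	-0.01	0.02	-0.01	0.01	0.01	0.02
cg13408519	-0.01	0.01	-0.01	0.01	-0.02	-0.01	0.00	0.00	0.00	0.00	0.03	0.01	-0.01	0.46
cg12604181	0.00	0.00	0.00	0.54	0.09	0.01	0.01	0.00	-0.01	0.00	0.01	-0.01	-0.02	0.00
cg18404925	-0.03	-0.01	0.00	0.06	0.63	0.03	-0.01	-0.01	0.00	0.03	0.02	0.01	-0.02	-0.02
cg13978347	0.04	-0.02	0.02	-0.01	0.01	0.01	0.03	0.02	-0.05	-0.04	0.02	-0.71	-0.03	-0.01
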