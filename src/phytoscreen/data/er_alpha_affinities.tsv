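ligand	affinity_kcal_mol
Hydroxytamoxifen	-9.7
Caryophyllene	-8.4
Caryophyllene oxide	-8.4
Humulene	-8.3
14-Hydroxy-9-epi-(E)-caryophyllene	-8.2
Calamenene	-8.0
Muurola-4,10(14)-dien-8beta-ol	-7.9
Nerolidol	-7.9
Copaborneol	-7.8
Copaane	-7.7
Linalyl anthranilate	-7.2
Eucalyptol	-6.3
Terpineol	-6.2
Limonenel	-6.1
(E)-beta-ocimene	-5.4
(Z)-beta-ocimene	-5.3
Myrcene	-5.1
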