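peak	rt_min	compound	area
1	14.5	Benzaldehyde	52096
2	15.7	Myrcene	63902
3	17.6	Limonene	5248363
4	17.8	Eucalyptol	2177857
5	17.9	Ocimene <(Z)-, beta->	135011
6	18.4	Ocimene <(E)-, beta->	61578
7	20.9	Linalyl anthranilate	83586
8	25.4	Terpineol <alpha->	129922
9	34.0	Copaene <alpha->	110063
10	36.0	Caryophyllene <(E)->	572209
11	37.4	Humulene <alpha->	72787
12	40.2	Calamenene <alpha->	88207
13	41.5	Nerolidol <(E)->	460010
14	42.8	Caryophyllene oxide	637587
15	43.6	Copaborneol	90736
16	44.4	Muurola-4,10(14)-diene-1-1-beta-ol	119809
17	44.8	Caryophyllene <14-hydroxy-9-epi-(E)->	131421
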