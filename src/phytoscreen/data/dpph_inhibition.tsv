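concentration_ug_ml	response_pct	sem_pct
3.1	24	2
6.3	30	3
12.5	44	1
25	53	3
50	55	2
100	61	2
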