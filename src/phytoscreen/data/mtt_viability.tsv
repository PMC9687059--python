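concentration_ug_ml	hepg2_pct	hepg2_sem	mcf7_pct	mcf7_sem	mcf12a_pct	mcf12a_sem
1	98.3	0.3	98.5	0.4	99.5	0.2
2	97.2	0.4	96.2	0.3	97.1	0.3
10	89.3	0.5	89.5	0.3	93.2	0.5
25	82.3	0.4	84.3	0.3	91.2	0.5
50	78.3	0.2	78.7	0.3	90.1	0.3
75	72.1	0.2	72.4	0.2	89.2	0.5
100	68.3	0.5	67.3	0.4	89.1	0.4
200	62.2	0.5	58.3	0.4	88.3	0.2
250	54.7	0.3	52.6	0.3	87.8	0.3
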