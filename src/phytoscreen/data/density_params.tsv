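element	rho_cnt	zeta	atomic_number
H	2.148062	3.779452	1
C	36.869463	6.141610	6
N	79.638041	7.369932	7
O	151.754711	8.598254	8
S	77.272279	6.866005	16
P	43.992301	6.047124	15
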