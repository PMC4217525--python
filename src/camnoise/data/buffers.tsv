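name	B_T_uM	k_plus_per_uM_ms	k_minus_per_ms	cv	reference
CaM	24	0.1	0.038	0.001	Smith et al.
TnC	140	0.12	0.023	<0.000	Uttenweiler et al.
PV	1000	0.25	0.001	<0.000	Jiang et al.
EGTA	100	0.0015	0.00094	<0.000	Uttenweiler et al.
Fluo-4	100	0.236	0.175	<0.000	Uttenweiler et al.
OGB-5N	100	0.17	5.6	<0.000	Novo et al.
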