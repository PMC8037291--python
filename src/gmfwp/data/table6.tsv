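# Measurement results, tomograph B (Philips Ingenia 1.5 T).
# EHP-50F analyzer (WP mode, magnetic field, full scale 100 uT).
sequence	distance_cm	height_cm	position_label	curve_id	index_percent	instrument
B1	0	100		RL_B	1389	EHP-50F
B1	0	100		LOW_AL_B	45.0	EHP-50F
B1	0	100		HIGH_AL_B	45.6	EHP-50F
B1		100	OP	RL_B	22.5	EHP-50F
B1		100	OP	LOW_AL_B	0.70	EHP-50F
B1		100	OP	HIGH_AL_B	0.60	EHP-50F
B2	0	100		RL_B	2356	EHP-50F
B2	0	100		LOW_AL_B	76.0	EHP-50F
B2	0	100		HIGH_AL_B	72.5	EHP-50F
B2	40	100		RL_B	401	EHP-50F
B2	40	100		LOW_AL_B	13.0	EHP-50F
B2	40	100		HIGH_AL_B	12.0	EHP-50F
B2	100	100		RL_B	83	EHP-50F
B2	100	100		LOW_AL_B	2.50	EHP-50F
B2	100	100		HIGH_AL_B	2.10	EHP-50F
B2		100	OP	RL_B	51	EHP-50F
B2		100	OP	LOW_AL_B	1.57	EHP-50F
B2		100	OP	HIGH_AL_B	1.25	EHP-50F
B2	0	160		RL_B	1332	EHP-50F
B2	0	160		LOW_AL_B	40.1	EHP-50F
B2	0	160		HIGH_AL_B	40.8	EHP-50F
B2	40	160		RL_B	317	EHP-50F
B2	40	160		LOW_AL_B	9.70	EHP-50F
B2	40	160		HIGH_AL_B	9.17	EHP-50F
B2	100	160		RL_B	66	EHP-50F
B2	100	160		LOW_AL_B	2.00	EHP-50F
B2	100	160		HIGH_AL_B	1.65	EHP-50F
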