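# Measurement results, tomograph C (Siemens Magnetom Aera 1.5 T).
# EHP-50F analyzer (WP mode, magnetic field, full scale 100 uT).
sequence	distance_cm	height_cm	position_label	curve_id	index_percent	instrument
C1	0	100		RL_B	2032	EHP-50F
C1	0	100		LOW_AL_B	78.9	EHP-50F
C1	0	100		HIGH_AL_B	86.5	EHP-50F
C2	0	100		RL_B	2642	EHP-50F
C2	0	100		LOW_AL_B	88.0	EHP-50F
C2	0	100		HIGH_AL_B	92.0	EHP-50F
C2	50	100		RL_B	338	EHP-50F
C2	50	100		LOW_AL_B	11.4	EHP-50F
C2	50	100		HIGH_AL_B	10.7	EHP-50F
C2	100	100		RL_B	100	EHP-50F
C2	100	100		LOW_AL_B	3.36	EHP-50F
C2	100	100		HIGH_AL_B	2.82	EHP-50F
C2	150	100		RL_B	44.4	EHP-50F
C2	150	100		LOW_AL_B	1.51	EHP-50F
C2	150	100		HIGH_AL_B	1.21	EHP-50F
C2		100	REAR	RL_B	916	EHP-50F
C2		100	REAR	LOW_AL_B	31.0	EHP-50F
C2		100	REAR	HIGH_AL_B	29.5	EHP-50F
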