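# Measurement results, tomograph A (Philips Panorama 1 T).
# ELT-400 probe in standalone display mode (Exposure STD ICNIRP 1998 General
# Public, Range Low, Low Cut 30 Hz, Detector STND) and EHP-50F analyzer
# (WP mode, magnetic field, full scale 100 uT).  Indices in percent.
sequence	distance_cm	height_cm	position_label	curve_id	index_percent	instrument
A1	0	100		RL_B	46.6	ELT-400
A2	0	100		RL_B	76.0	ELT-400
A2	0	100		RL_B	70.0	EHP-50F
A2	0	100		LOW_AL_B	2.0	EHP-50F
A2	0	100		HIGH_AL_B	1.5	EHP-50F
A2	50	100		RL_B	7.0	ELT-400
A2	50	100		RL_B	9.0	EHP-50F
A2	50	100		LOW_AL_B	0.3	EHP-50F
A2	50	100		HIGH_AL_B	0.3	EHP-50F
A2	100	100		RL_B	2.4	ELT-400
A2	100	100		RL_B	2.4	EHP-50F
A2	100	100		LOW_AL_B	0.1	EHP-50F
A2	100	100		HIGH_AL_B	0.1	EHP-50F
A2	150	100		RL_B	1.7	ELT-400
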