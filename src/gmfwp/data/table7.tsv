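# Measurement results, tomograph B (Philips Ingenia 1.5 T).
# ELT-400 probe, postprocessing of raw data acquired from the analogue
# outputs (Field Strength mode 320 uT, Range Low, Low Cut 30 Hz).
sequence	distance_cm	height_cm	position_label	curve_id	index_percent	instrument
B1	0	100		RL_B	1423	ELT-400-chain
B1	0	100		LOW_AL_B	52.4	ELT-400-chain
B1	0	100		HIGH_AL_B	53.2	ELT-400-chain
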