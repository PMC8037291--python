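# Measurement results, tomograph A (Philips Panorama 1 T).
# ELT-400 probe, postprocessing of raw data acquired from the analogue
# outputs (Field Strength mode 320 uT, Range Low, Low Cut 30 Hz).
sequence	distance_cm	height_cm	position_label	curve_id	index_percent	instrument
A2	0	100		RL_B	69.5	ELT-400-chain
A2	0	100		LOW_AL_B	3.36	ELT-400-chain
A2	0	100		HIGH_AL_B	3.56	ELT-400-chain
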