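PID_ERBB2_ERBB3	ERBB2/ERBB3 signalling events (representative membership)	GRB2	ERBB2	ERBB3	NRG1	SHC1	SOS1	PIK3CA	PIK3CB	PIK3R1	AKT1	RAF1	MAP2K1	MAPK1
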