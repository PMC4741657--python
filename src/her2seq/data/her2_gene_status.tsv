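sample_id	erbb2_mutation	erbb2_copy_status	mutated	amplification_value	grb2_mrna	her2_3_pathway
OS191		Amp. (14.53)	No	14.53	0.674	0.447
OS226	p.P420fs (0.22)	Amp. (13.99)	Yes	13.99	0.144	-0.591
OS230		Amp. (22.38)	No	22.38	0.897	0.178
OS240	S413L (0.01)	Amp. (16.39)	Yes	16.39	0.431	-0.136
OS244		Amp. (12.36)	No	12.36	0.286	-0.037
OS245		Amp. (16.04)	No	16.04	N/A	N/A
OS256	S72A (0.01)	Amp. (25.93)	Yes	25.93	N/A	N/A
OS257		Amp. (30.13)	No	30.13	1.716	-0.470
OS265		Amp. (14.09)	No	14.09	1.189	-0.156
OS306		Amp. (13.8)	No	13.8	N/A	N/A
OS251	P562S (0)	Amp. (20)	Yes	20	-0.024	-0.593
OS314		Amp. (9.52)	No	9.52	1.388	-0.485
OS321	Q692X (0.02)	Amp. (5.39)	Yes	5.39	0.541	-0.206
OS337		Amp. (3.99)	No	3.99	0.301	0.040
OS266	L755S (0.19)	None	Yes	2	0.144	-0.591
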