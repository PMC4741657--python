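sample_id	protein_change	ngs_vaf_pct	ngs_alt	ngs_ref	control_pct	control_fam	control_vic	sample_pct	sample_fam	sample_vic
226	P420fs	0.2172	16	7365	0.0103	3.752	36312	0.4523	11.05	2442.6
240	S413L	1.1954	96	8668	0.0670	35.173	52471	1.2859	558.09	45731
256	S72A	0.7457	42	5590	0.0766	17.506	22848	0.8343	190.36	22186
251	P562S	0.4345	38	8475	0.0197	7.409	37529	0.2603	143.46	55095
321	Q692X	1.6919	38	2208	0.0023	0.601	26319	1.2574	433.51	34475
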