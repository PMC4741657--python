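patient_number	patient_id	age	menopausal_status	er	pr	her2	histologic_grade	nuclear_grade	stage	prior_regimens	biopsy_site
1	OS173	47	Pre	0	0	0	2	2	4	4	Skin
2	OS181	35	Pre	0	0	0	3	3	3A	5	Pleura
3	OS188	42	Pre	0	0	0	3	3	1A	6	Lung
4	OS191	49	Pre	0	0	1	1	2	2A	4	Pleura
5	OS200	30	Pre	1	0	0	3	3	1A	4	Pleura
6	OS209	47	Pre	0	0	0	3	3	3C	6	Skin
7	OS226	51	Pre	0	0	1	3	3	3A	7	LN
8	OS228	38	Pre	0	0	0	N/A	N/A	4	5	Skin
9	OS230	45	Pre	0	0	1	N/A	N/A	1A	5	Breast
10	OS235	55	Post	0	0	0	N/A	N/A	4	6	Liver
11	OS240	56	Post	0	0	1	N/A	N/A	4	3	Breast
12	OS244	46	Pre	0	1	1	N/A	N/A	4	4	Pleura
13	OS245	52	Post	0	0	1	3	3	4	5	Breast
14	OS250	38	Pre	1	0	0	N/A	N/A	2A	5	Breast
15	OS251	40	Pre	0	0	1	2	3	3A	6	LN
16	OS255	44	Pre	1	1	0	3	3	2B	7	Liver
17	OS256	58	Post	0	0	1	3	2	0	7	Liver
18	OS257	56	Post	1	1	1	N/A	N/A	4	7	Breast
19	OS259	42	Pre	0	0	0	2	2	3A	8	Breast
20	OS262	64	Post	0	0	0	N/A	N/A	4	4	Breast
21	OS263	63	Post	1	0	0	N/A	N/A	2A	5	Liver
22	OS265	32	Pre	0	0	1	2	2	4	6	Breast
23	OS266	50	Pre	1	1	0	2	2	4	6	Ovary
24	OS287	52	Post	1	0	0	3	3	3C	4	Pleura
25	OS291	42	Pre	1	0	0	N/A	N/A	3C	7	Pleura
26	OS306	41	Pre	1	1	0	2	2	3C	6	Pleura
27	OS314	63	Post	0	0	1	3	3	4	6	Breast
28	OS321	41	Pre	0	0	1	2	2	2A	5	Breast
29	OS324	47	Pre	1	0	0	3	3	3A	5	Liver
30	OS333	26	Pre	0	1	0	2	2	2A	4	Chest wall
31	OS336	33	Pre	0	0	0	3	3	3C	3	Breast
32	OS337	29	Pre	1	1	1	N/A	N/A	4	6	Breast
33	OS349	36	Pre	1	0	0	N/A	N/A	3C	6	LN
34	OS370	37	Pre	1	1	0	3	3	3A	4	Liver
35	OS375	40	Pre	0	0	0	N/A	N/A	4	7	Breast
36	OS410	47	Pre	0	0	0	3	3	2A	3	Breast
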