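taxon	geography	clade	subclade	two_c_pg	locus_pairs	locus_uncertain	native_cn	native_sd	panicum_cn	panicum_sd	paspalum_cn	paspalum_sd	setaria_cn	setaria_sd	euclasta_cn	euclasta_sd
H. bogdanii	Central Asia	I-Eurasian	Eurasian	9.48	1	1	9320	1989	17	5	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.
H. californicum	North America	I-American	californicum	8.19	1	1	8478	2516	12	8	n.d.	n.d.	n.d.	n.d.	19	8
H. chilense	Central Argentina	I-American	core	8.77	2	0	21665	n.d.	36	n.d.	98	n.d.	n.d.	n.d.	n.d.	n.d.
H. comosum	Patagonia	I-American	core	8.97	n.d.	0	3929	n.d.	10	n.d.	12	n.d.	4	n.d.	60	n.d.
H. cordobense	Central Argentina	I-American	muticum/cordobense	9.19	2	1	4122	n.d.	14	n.d.	9	n.d.	n.d.	n.d.	14	n.d.
H. erectifolium	Central Argentina	I-American	core	9.49	2	1	22282	n.d.	n.d.	n.d.	45	n.d.	4	n.d.	n.d.	n.d.
H. euclaston	Central Argentina	I-American	core	6.85	2	1	6416	1798	n.d.	n.d.	134	177	n.d.	n.d.	n.d.	n.d.
H. flexuosum	Central Argentina	I-American	core	8.51	2	1	13980	n.d.	16	n.d.	59	n.d.	n.d.	n.d.	n.d.	n.d.
H. intercedens	North America	I-American	core	7.01	2	1	12779	10846	n.d.	n.d.	9	9	n.d.	n.d.	n.d.	n.d.
H. muticum	Central Argentina	I-American	muticum/cordobense	9.57	1	1	3498	1933	15	7	n.d.	n.d.	n.d.	n.d.	28	31
H. patagonicum subsp. magellanicum	Patagonia	I-American	core	9.33	2	0	13212	n.d.	25	n.d.	39	n.d.	n.d.	n.d.	73	n.d.
H. patagonicum subsp. mustersii	Patagonia	I-American	core	8.77	2	0	1689	n.d.	15	n.d.	18	n.d.	n.d.	n.d.	n.d.	n.d.
H. patagonicum subsp. patagonicum	Patagonia	I-American	core	9.46	2	0	2337	291	36	26	59	27	n.d.	n.d.	132	n.d.
H. patagonicum subsp. setifolium	Patagonia	I-American	core	9.61	2	1	10996	6986	23	3	10	8	13	n.d.	134	20
H. pubiflorum	Patagonia	I-American	core	8.70	2	1	3830	2727	23	8	6	3	n.d.	n.d.	26	27
H. pusillum	North America	I-American	core	7.16	2	1	12488	2802	n.d.	n.d.	401	n.d.	n.d.	n.d.	n.d.	n.d.
H. roshevitzii	Central Asia	I-Eurasian	Eurasian	9.69	1	1	11138	880	18	9	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.
H. stenostachys	Central Argentina	I-American	core	9.38	2	1	7257	4683	26	n.d.	50	38	16	7	474	n.d.
H. gussoneanum	Western Eurasia	Xa	n.d.	10.41	1	0	5031	3101	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.
H. marinum	Western Eurasia	Xa	n.d.	9.10	1	1	14026	8769	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.
H. murinum subsp. glaucum	Western Eurasia	Xu	n.d.	9.11	2	1	31342	13353	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.
H. vulgare subsp. spontaneum	Western Eurasia	H	n.d.	10.59	2	0	24415	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.
H. vulgare subsp. vulgare	Western Eurasia	H	n.d.	10.59	2	0	26556	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.
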