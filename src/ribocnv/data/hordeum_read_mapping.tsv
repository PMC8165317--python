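sample	lineage	genome_size_mb	n_reads	m_mapped	proportion_pct	genome_space_mb	genome_space_kb	copy_number
H. vulgare cv. Morex	H	10357.02	35000000	178318	0.51	52.781	52781	9100
H. vulgare cv. BW457	H	10357.02	34190711	251901	0.74	76.306	76306	13150
H. vulgare cv. AAC Synergy	H	10357.02	35000000	124428	0.36	36.820	36820	6350
H. vulgare cv. Igri	H	10357.02	35000000	116486	0.33	34.470	34470	5940
H. vulgare subsp. spontaneum	H	10435.26	35000000	206923	0.59	61.694	61694	10640
H. murinum subsp. glaucum BCC2017	Xu	8909.58	31000000	158437	0.51	45.536	45536	7850
H. marinum BCC2001	Xa	8899.80	48000000	112020	0.23	20.770	20770	3580
H. gussoneanum BCC2012	Xa	10180.98	54086101	71061	0.13	13.376	13376	2310
H. bogdanii BCC2063	I-Eurasian	9271.44	47328373	73152	0.15	14.330	14330	2470
H. pubiflorum BCC2028	I-American	8508.60	44000000	89665	0.20	17.339	17339	2990
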