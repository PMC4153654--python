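protein	accession	peptide	site_source	site_human	log2_ns_wt	log2_ls_wt	significant_ns	significant_ls	quadrant	n_psms
receptor B-like	PROTB	MEGVV(pY)ADLR	Y26	Y29	2.95	1.77	True	True	shared_up	1
kinase A-like	PROTA	DDSA(pY)LQGK	Y23	Y21	1.50	0.40	True	False	ns_only_up	1
kinase A-like	PROTA	NQSE(pY)FDTK	Y32	Y30	1.20		True	False	ns_only_up	1
kinase C-like; kinase D-like	PROTC;PROTD	GGE(pY)TVVMK	Y5; Y12	Y5; Y11	0.00	1.92	False	True	ls_only_up	1
receptor B-like	PROTB	TSPLYQDEK	Y16	Y19	-1.18	-0.48	True	False	ns_only_down	1
kinase A-like	PROTA	SAMPD(pY)INK	Y15	Y13	-1.91	-1.47	True	True	shared_down	2
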