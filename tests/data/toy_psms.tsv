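PSM ID	Sequence	Modifications	Protein Group Accessions	Protein Descriptions	Decoy	Rank	IonScore	DeltaM [ppm]	RT [min]	Light	Medium	Heavy	Medium/Light	Heavy/Light	phosphoRS Site Probabilities
NP001	LAGELFNK	N-Term(Dimethyl); K8(Dimethyl)	PROTA	kinase A-like	False	1	48	-0.8	30	100	120	200			
NP002	VSTDNPEAGK	N-Term(Dimethyl); K10(Dimethyl)	PROTB	receptor B-like	False	1	48	-0.8	31	100	125	210			
NP003	GLSDEIANK	N-Term(Dimethyl); K9(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	32	100	130	220			
NP004	TTPELGFNR	N-Term(Dimethyl)	KRTL1	keratin-like contaminant protein	False	1	48	-0.8	33	100	145	250			
NP005	EGVNDNEEGFFSAR	N-Term(Dimethyl)	VTGL1	vitellogenin-like contaminant protein	False	1	48	-0.8	34	100	150	260			
NP006	AVFPSIVGR	N-Term(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	35	100	138	235			
NP007	LAGELFNK	N-Term(Dimethyl); K8(Dimethyl)	PROTA	kinase A-like	False	1	48	-0.8	36	100	138	235			
NP008	VSTDNPEAGK	N-Term(Dimethyl); K10(Dimethyl)	PROTB	receptor B-like	False	1	48	-0.8	37	100	138	235			
NP009	GLSDEIANK	N-Term(Dimethyl); K9(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	38	100	138	235			
NP010	TTPELGFNR	N-Term(Dimethyl)	KRTL1	keratin-like contaminant protein	False	1	48	-0.8	39	100	138	235			
NP011	EGVNDNEEGFFSAR	N-Term(Dimethyl)	VTGL1	vitellogenin-like contaminant protein	False	1	48	-0.8	40	100	138	235			
NP012	AVFPSIVGR	N-Term(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	41	100	138	235			
NP013	LAGELFNK	N-Term(Dimethyl); K8(Dimethyl)	PROTA	kinase A-like	False	1	48	-0.8	42	100	138	235			
NP014	VSTDNPEAGK	N-Term(Dimethyl); K10(Dimethyl)	PROTB	receptor B-like	False	1	48	-0.8	43	100	138	235			
NP015	GLSDEIANK	N-Term(Dimethyl); K9(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	44	100	138	235			
NP016	TTPELGFNR	N-Term(Dimethyl)	KRTL1	keratin-like contaminant protein	False	1	48	-0.8	45	100	138	235			
NP017	EGVNDNEEGFFSAR	N-Term(Dimethyl)	VTGL1	vitellogenin-like contaminant protein	False	1	48	-0.8	46	100	138	235			
NP018	AVFPSIVGR	N-Term(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	47	100	138	235			
NP019	LAGELFNK	N-Term(Dimethyl); K8(Dimethyl)	PROTA	kinase A-like	False	1	48	-0.8	48	100	138	235			
NP020	VSTDNPEAGK	N-Term(Dimethyl); K10(Dimethyl)	PROTB	receptor B-like	False	1	48	-0.8	49	100	138	235			
NP021	GLSDEIANK	N-Term(Dimethyl); K9(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	50	100	138	235			
NP022	TTPELGFNR	N-Term(Dimethyl)	KRTL1	keratin-like contaminant protein	False	1	48	-0.8	51	100	138	235			
NP023	EGVNDNEEGFFSAR	N-Term(Dimethyl)	VTGL1	vitellogenin-like contaminant protein	False	1	48	-0.8	52	100	138	235			
NP024	AVFPSIVGR	N-Term(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	53	100	138	235			
NP025	LAGELFNK	N-Term(Dimethyl); K8(Dimethyl)	PROTA	kinase A-like	False	1	48	-0.8	54	100	138	235			
NP026	VSTDNPEAGK	N-Term(Dimethyl); K10(Dimethyl)	PROTB	receptor B-like	False	1	48	-0.8	55	100	138	235			
NP027	GLSDEIANK	N-Term(Dimethyl); K9(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	56	100	138	235			
NP028	TTPELGFNR	N-Term(Dimethyl)	KRTL1	keratin-like contaminant protein	False	1	48	-0.8	57	100	138	235			
NP029	EGVNDNEEGFFSAR	N-Term(Dimethyl)	VTGL1	vitellogenin-like contaminant protein	False	1	48	-0.8	58	100	138	235			
NP030	AVFPSIVGR	N-Term(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	59	100	138	235			
NP031	LAGELFNK	N-Term(Dimethyl); K8(Dimethyl)	PROTA	kinase A-like	False	1	48	-0.8	60	100	138	235			
NP032	VSTDNPEAGK	N-Term(Dimethyl); K10(Dimethyl)	PROTB	receptor B-like	False	1	48	-0.8	61	100	138	235			
NP033	GLSDEIANK	N-Term(Dimethyl); K9(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	62	100	138	235			
NP034	TTPELGFNR	N-Term(Dimethyl)	KRTL1	keratin-like contaminant protein	False	1	48	-0.8	63	100	138	235			
NP035	EGVNDNEEGFFSAR	N-Term(Dimethyl)	VTGL1	vitellogenin-like contaminant protein	False	1	48	-0.8	64	100	138	235			
NP036	AVFPSIVGR	N-Term(Dimethyl)	ACTL1	actin-like contaminant protein	False	1	48	-0.8	65	100	138	235			
NP037	LAGELFNK	N-Term(Dimethyl); K8(Dimethyl)	PROTA	kinase A-like	False	1	48	-0.8	66	100	138	235			
PP01a	SAMPDYINK	N-Term(Dimethyl); K9(Dimethyl); Y6(Phospho)	PROTA	kinase A-like	False	1	52	1.2	42	1000	367.2077129	848.3084024			S(1): 1; Y(6): 99
PP01b	SAMPDYINK	N-Term(Dimethyl); K9(Dimethyl); Y6(Phospho)	PROTA	kinase A-like	False	1	52	1.2	42	1000	367.2077129	848.3084024			S(1): 1; Y(6): 99
PP02a	MEGVVYADLR	N-Term(Dimethyl); Y6(Phospho)	PROTB	receptor B-like	False	1	52	1.2	42	1000	10663.93707	8014.767983			Y(6): 100
PP03a	TSPLYQDEK	N-Term(Dimethyl); K9(Dimethyl); Y5(Phospho)	PROTB	receptor B-like	False	1	52	1.2	42	1000	609.0650674	1684.897416			T(1): 15; S(2): 25; Y(5): 60
PP04a	DDSAYLQGK	N-Term(Dimethyl); K9(Dimethyl); Y5(Phospho)	PROTA	kinase A-like	False	1	52	1.2	42	1000	3903.229432	3100.84359			S(3): 2; Y(5): 98
PP04b	DDSAYLQGK	N-Term(Dimethyl); K9(Dimethyl); Y5(Phospho)	PROTA	kinase A-like	False	1	52	1.2	42	1000	11040	18800			S(3): 30; Y(5): 70
PP05a	GGEYTVVMK	N-Term(Dimethyl); K9(Dimethyl); Y4(Phospho)	PROTC;PROTD	kinase C-like; kinase D-like	False	1	52	1.2	42	1000	1380	8892.941879			Y(4): 97; T(5): 3
PP06a	NQSEYFDTK	N-Term(Dimethyl); K9(Dimethyl); Y5(Phospho)	PROTA	kinase A-like	False	1	52	1.2	42	1000	3170.40746				S(3): 2; Y(5): 96; T(8): 2
DEC01	KNFLEGAL	N-Term(Dimethyl); K1(Dimethyl)	DECOY_PROTA	decoy of PROTA	True	1	45	0.3	55	100	140	230			
REJ01	LAGELFNK	N-Term(Dimethyl); K8(Dimethyl)	PROTA	kinase A-like	False	1	10	0.5	0	100	138	235			
REJ02	VSTDNPEAGK	N-Term(Dimethyl); K10(Dimethyl)	PROTB	receptor B-like	False	1	40	15	0	100	138	235			
REJ03	SAYK	N-Term(Dimethyl); K4(Dimethyl); Y3(Phospho)	PROTA	kinase A-like	False	1	50	0	0	100	138	235			S(1): 1; Y(3): 99
REJ04	GLSDEIANK	N-Term(Dimethyl); K9(Dimethyl)	ACTL1	actin-like contaminant protein	False	2	35	0.1	0	100	138	235			
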