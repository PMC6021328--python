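id	age	sex	karnofsky	location	hemisphere	os_months	event	surgery	chemotherapy
GBM1	80	M	NA	Temporal	L	6	1	total	NA
GBM2	75	M	80	Fronto-temporal	R	22	1	total	Stupp
GBM3	61	F	90	Parietal	R	83	1	total	Stupp
GBM4	73	M	100	Temporal	L	19	1	partial	Stupp
GBM5	38	M	90	Frontal	R	15	1	total	Stupp
GBM6	49	F	60	Frontal	R	30	0	partial	Stupp
GBM7	41	M	40	Temporal	R	11	1	partial	Stupp
GBM8	57	M	90	Tempo-parietal	R	6	1	total	Stupp
GBM9	72	M	90	Temporal	R	28	0	partial	Stupp
GBM10	62	M	100	Parietal	R	28	0	total	Stupp
GBM11	71	M	80	Temporal	R	27	1	partial	Stupp
GBM12	50	F	100	Temporal	R	13	1	total	Stupp
GBM13	72	F	70	Temporal	R	9	1	partial	Stupp
GBM14	78	F	100	Frontal	R	6	1	total	None
GBM15	61	F	100	Frontal	R	25	0	total	Stupp
GBM16	54	M	100	Fronto-parietal	R	2	1	total	Stupp
GBM17	52	M	80	Frontal	R	63	1	partial	Stupp
GBM18	57	F	90	Temporal	R	10	1	partial	Stupp
GBM19	68	M	90	Occipital	L	10	1	total	Stupp
GBM20	82	F	80	Frontal	L	7	1	total	None
GBM21	77	M	70	Temporal	R	6	1	partial	None
GBM22	69	F	100	Frontal	L	8	1	total	Stupp
GBM23	24	F	80	Frontal	L	21	1	partial	Stupp
G97	53	M	80	Temporal	R	21	1	total	Stupp
G94	79	F	80	Temporal	R	9	1	partial	None
G93	63	M	80	Occipital	R	29	1	total	Stupp
G92	54	F	80	Parietal	R	15	1	total	Stupp
G91	73	F	60	Occipital	R	13	1	partial	Stupp
G90	57	F	60	Parietal	L	5	1	biopsy	None
G89	51	M	80	Temporal	R	2	1	partial	None
G88	71	M	80	Parietal	R	8	1	partial	Stupp
G87	45	M	80	Temporal	L	16	1	partial	Stupp/Sequential
G83	75	M	70	Temporal	R	10	1	partial	None
G82	78	M	70	Frontal	R	2	1	biopsy	None
G81	62	F	70	Frontal	R	13	1	partial	Stupp
G80	43	M	80	Frontal	R	18	1	total	Stupp
G79	71	F	60	Occipital	R	6	1	biopsy	None
G73	78	F	60	Parietal	L	4	1	biopsy	None
G72	77	F	70	Temporal	L	1	1	partial	None
G71	66	F	60	Parietal	R	10	1	partial	Sequential
G70	56	F	80	Occipital	L	21	1	partial	Stupp
G68	72	M	70	Insular	L	26	1	total	Stupp
G67	68	F	80	Parietal	R	35	1	partial	Stupp
G66	60	M	80	Occipital	R	14	1	total	Stupp
G65	69	F	60	Parietal	L	1	1	partial	None
G64	57	M	60	Occipital	L	8	1	partial	Sequential
G63	61	F	60	Insular	R	13	1	partial	Sequential
G62	57	F	90	Occipital	R	18	1	total	Stupp
G57	34	M	90	Frontal	R	8	1	total	Stupp
G56	65	M	80	Frontal	L	13	1	partial	Stupp
G55	54	F	80	Frontal	R	17	1	partial	Stupp
G54	65	F	60	Parietal	L	6	1	partial	None
G53	74	M	60	Frontal	L	29	1	total	Stupp
G52	56	M	90	Frontal	L	21	1	biopsy	Stupp
G51	60	M	60	Temporal	R	2	1	biopsy	None
G50	84	M	70	Temporal	R	11	1	partial	None
G46	62	M	60	Frontal	L	3	1	partial	None
G45	76	F	60	Temporal	R	10	1	partial	None
G44	48	M	80	Frontal	L	22	1	partial	PCV
G43	67	F	70	Temporal	R	7	1	partial	None
G42	67	M	80	Temporal	R	2	1	partial	None
G41	44	F	60	Frontal	R	14	1	biopsy	Sequential
G40	45	F	80	Frontal	R	15	1	partial	BCNU+TMZ
G39	70	F	50	Frontal	R	18	1	partial	Stupp
G37	70	M	80	Temporal	R	32	1	total	Stupp
G35	50	F	80	Frontal	L	2	1	partial	None
G34	69	M	60	Temporal	R	5	1	biopsy	None
G31	71	F	90	Frontal	R	7	1	partial	None
G30	71	F	70	Temporal	R	9	1	biopsy	None
G29	49	F	80	Parietal	L	12	1	biopsy	Sequential
G25	68	M	80	Frontal	L	6	1	partial	Stupp
G23	50	F	70	Frontal	R	14	1	biopsy	Stupp
G17	30	F	90	Temporal	R	67	1	partial	Sequential
G15	79	M	80	Parietal	L	5	1	total	Sequential
G14	69	F	70	Frontal	R	0	1	biopsy	None
G13	39	F	90	Frontal	R	20	1	partial	Sequential
G12	74	M	70	Temporal	R	1	1	biopsy	None
G10	35	F	80	Temporal	L	15	1	partial	Stupp
G8	67	F	90	Deep	NA	9	1	partial	Stupp
G6	70	F	80	Temporal	R	19	1	partial	Stupp
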