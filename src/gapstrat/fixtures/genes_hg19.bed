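chr7	54560000	54610000	VSTM2A	0	+
chr7	54820000	54840000	SEC61G	0	-
chr7	55086000	55324000	EGFR	0	+
chr7	55433000	55510000	LANCL2	0	+
chr7	55610000	55650000	VOPP1	0	-
chr12	57870000	57895000	MARS	0	+
chr12	57910000	57930000	DCTN2	0	+
chr12	57940000	57975000	KIF5A	0	+
chr12	57977000	57990000	PIP4K2C	0	-
chr12	57993000	58000000	DTX3	0	+
chr12	58001000	58015000	ARHGEF25	0	-
chr12	58016000	58030000	SLC26A10	0	+
chr12	58031000	58045000	B4GALNT1	0	+
chr12	58110000	58125000	OS9	0	+
chr12	58128000	58140000	AGAP2	0	-
chr12	58142000	58150000	CDK4	0	-
chr12	58151000	58156000	CYP27B1	0	-
chr12	58157000	58161000	METTL1	0	+
chr12	58165000	58180000	TSFM	0	+
chr12	58191000	58210000	AVIL	0	-
chr12	58213000	58240000	CTDSP2	0	+
chr12	58245000	58255000	METT21B	0	+
chr12	69000000	69030000	ATP23	0	+
chr12	69201000	69239000	MDM2	0	+
chr12	69244000	69320000	CPM	0	-
chr4	53900000	54050000	SCFD2	0	-
chr4	54240000	54320000	FIP1L1	0	+
chr4	55095000	55165000	PDGFRA	0	+
chr4	55524000	55607000	KIT	0	+
chr1	204040000	204080000	SOX13	0	+
chr1	204085000	204100000	ETNK2	0	+
chr1	204120000	204135000	REN	0	-
chr1	204159000	204165000	KISS1	0	+
chr1	204170000	204185000	GOLT1A	0	-
chr1	204190000	204240000	PLEKHA6	0	+
chr1	204390000	204460000	PIK3C2B	0	+
chr1	204485000	204528000	MDM4	0	+
chr1	204600000	204640000	LRRN2	0	+
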