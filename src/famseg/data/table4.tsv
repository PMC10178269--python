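family_id	gene	cdna	sift	polyphen2	loftool	mutation_assessor	mutation_taster	fathmm	cadd_phred	loftool_suspect
MTC_1	PTPRS	c.3548A>G	D (0.019)	P (1)	PD (0.317)	M (2.5)	DC (1)	T (0.52)	33	0
MTC_3	TBC1D4	c.1862C>T	D (0.007)	PD (0.9)	B (0.771)	L (1.7)	DC (1)	T (0.95)	23.6	0
MTC_4	UBA7	c.1232G>A	T (0.96)	B (0.002)	B (0.935)	L (1.2)	DC (1)	T(0.04)	20.7	0
MTC_4	NICN1	c.56G>A	D (0)	PD (0.99)	PD (0.403)	M (2.11)	DC (1)	T (1.82)	29.6	0
MTC_4	MROH2A	c.1736T>C	D (0.004)	---	---	---	DC (1)	T (0.56)	28.3	0
MTC_4	IL16	c.1712_1718del	---	---	PD (0.492)	---	---	---	22.8	0
MTC_4	DDX51	c.1262C>T	T (0.2)	B (0.44)	B (0.767)	L (1.83)	DC (1)	T (4.43)	22.3	0
MTC_4	CCDC134	c.217del	---	---	PD (0.373)	---	---	---	33	0
MTC_4	ANKRD24	c.2815G>C	D (0.047)	B (0.1)	B (0.852)	L (0.55)	DC (1)	T (1.32)	21.4	0
MTC_4	DNAH11	c.1915C>T	---	---	---	---	DC (1)	---	34	0
MTC_4	MAPK12	c.226C>T	D (0.01)	P (1)	B (0.778)	L (1.8)	DC (1)	T (−0.24)	32	0
MTC_5	ZNF19	c.548A>G	D (0.001)	PD (0.66)	B (0.78)	M (3.15)	DC (1)	T (−0.27)	22.7	0
MTC_5	USP40	c.3299C>A	T (0.063)	PD (0.718)	B (0.986)	M (2.71)	DC (1)	T (3.4)	23.3	0
MTC_5	MSH6	c.3226C>T	D (0.023)	PD (0.99)	PD (0.112)	M (2.29)	DC (1)	D (−2.03)	29.3	0
MTC_5	DGKQ	c.2296C>T	D (0.002)	P (1)	PD (0.367)	H (3.75)	DC (1)	T (1)	29.7	0
MTC_5	COL4A4	c.286G>A	T (0.14)	PD (0.85)	D (−2.67)	L (1.105)	DC (0.62)	D (−3.38)	23.2	1
NMTC_1	FOXM1	c.176C>A	D (0.001)	PD (0.99)	PD (0.0154)	M (2.82)	DC (0.99)	D (−3.17)	26.3	0
NMTC_1	EpCAM	c.928A>T	D (0.001)	P (1)	---	M (2.95)	DC (0.95)	T (−0.9)	23.3	0
NMTC_1	KRT39	c.858del	---	---	---	---	---	---	33	0
NMTC_1	BTBD16	c.253G>T	---	---	---	---	DC (1)	---	36	0
NMTC_2	CACNA2D1	c.3227A>C	D (0.004)	PD (0.99)	PD (0.258)	M (2.62)	DC (0.99)	T (3.14)	25.6	0
NMTC_2	SHISA6	c.1576C>T	D (0.017)	PD (0.99)	---	L (1.39)	DC (0.83)	---	25.1	0
NMTC_2	AATK	c.1342C>T	D (0)	P (1)	---	M (3.22)	DC (0.99)	D (−2.06)	25.4	0
NMTC_4	JMJD1C	c.3743A>G	D (0)	PD (0.99)	PD (0.0285)	M (1.97)	DC (0.99)	T (0.03)	25.3	0
NMTC_4	AGXT	c.827T>G	D (0)	PD (0.99)	PD (0.0556)	H (4.23)	DC (1)	D (−2.56)	28	0
NMTC_6	HOOK3	c.1448G>T	D (0.004)	PD (0.88)	PD (0.17)	M (2.1)	DC (1)	T (2.2)	24.6	0
NMTC_6	RNF20	c.1295A>C	D (0.002)	PD (0.9)	B (0.764)	M (2.01)	DC (0.99)	T (1.19)	23.1	0
NMTC_6	GGNBP2	c.317C>G	--	PD (0.98)	PD (0.157)	M (2.25)	DC (0.99)	---	26.3	0
NMTC_7	NKD1	c.1304T>C	D (0)	PD (0.99)	PD (0.0705)	L (1.38)	DC (1)	T(−1.09)	24.3	0
NMTC_7	ROBO1	c.926T>C	D (0.001)	PD (0.83)	B (0.687)	M (2.155)	DC (0.99)	T (−0.4)	26.6	0
NMTC_7	MYH10	c.4738G>A	D (0.013)	PD (0.86)	---	H (3.815)	DC (1)	D (−2.04)	26.6	0
NMTC_7	TTC28	c.3386C>T	D (0.013)	PD (0.83)	---	L (1.61)	DC (1)	T (−1.01)	25.4	0
NMTC_7	ZZEF1	c.6495C>A	T (0.1)	B (0.001)	PD (0.55)	L (0.345)	DC (0.83)	T (2.17)	20.2	0
NMTC_7	CLIC6	c.1363C>T	D (0)	PD (0.99)	---	L (1.9)	DC (1)	T (0.9)	29.9	0
NMTC_7	CSMD2	c.6649G>A	D (0)	PD (0.99)	PD (0.316)	M (2.745)	DC (1)	T 1.22)	31	0
NMTC_7	STK32A	c.637G>A	D (0)	PD (0.99)	B (0.87)	L (0.99)	DC (0.99)	T (1.83)	25.8	0
NMTC_7	TG	c.6753G>T	D (0)	PD (0.99)	B (0.858)	H (4.57)	DC (1)	T (−0.97)	32	0
NMTC_11	NTRK1	c.938T>A	D (0.001)	PD (0.98)	PD (0.0395)	M (2.285)	DC (1)	T (1.44)	27.6	0
NMTC_11	TNKS	c.1867C>A	D (0.024)	B (0.43)	PD (0.41)	M (2.545)	DC (1)	T (0.67)	23.8	0
NMTC_11	ANKRD35	c.2443T>C	---	---	B (0.99)	---	---	---	24.2	0
NMTC_11	OR51M1	c.336G>C	D (0)	---	PD (0.377)	H (3.73)	DC (1)	T (7.19)	24.6	0
NMTC_11	PPP6R2	c.2139G>A	---	---	---	---	DC (1)	---	47	0
NMTC_12	FNTB	c.1166G>A	---	---	---	---	DC (1)	---	45	0
NMTC_12	ITPR1	c.7808C>T	D (0)	PD (0.98)	PD (0.0141)	M (3.013)	DC (1)	T (0.81)	30	0
NMTC_12	PRKG1	c.1022G>A	D (0.001)	PD (0.98)	PD (0.0367)	L (1.53)	DC (1)	T (1.5)	28	0
NMTC_12	DENND2B	c.697_699del	---	---	PD (0.39)	---	---	---	21.6	0
NMTC_12	BMP1	c.2510T>C	D (0.001)	PD (0.98)	B (0.687)	M (2.99)	DC (1)	T (2.05)	26.8	0
NMTC_12	THSD7A	c.1969G>A	D (0)	P (1)	---	H (3.865)	DC (1)	D (−1.75)	31	0
NMTC_12	INSC	c.968G>T	D (0)	PD (0.99)	B (0.687)	L (1.04)	DC (1)	T (0.93)	26.9	0
NMTC_12	USH2A	c.12400G>A	D (0)	PD (0.99)	B (0.92)	M (3.425)	DC (1)	T (−1.02)	28.5	0
NMTC_13	MPPE1	c.605del	---	---	B (0.93)	---	---	---	31	0
NMTC_13	KTI12	c.623T>A	D (0.004)	P (1)	---	M (3.15)	DC (0.99)	T (1.23)	25	0
NMTC_13	BEAN1	c.360G>A	---	---	---	---	DC (1)	---	37	0
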