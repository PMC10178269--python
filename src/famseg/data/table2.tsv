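family_id	gene	position	cdna	protein	dbsnp	acmg_class	clin_sig	known_tc_gene	maf	consequence
MTC_1	PTPRS	chr19:5220272	NM_002850.4:c.3548A>G	p.Glu1183Gly	-	LP	NA(a,b)	No		missense
MTC_3	TBC1D4	chr13:75900504	NM_014832.5:c.1862C>T	p.Ser621Leu	rs888445750	VUS	NA(a,b)	No		missense
MTC_4	UBA7	chr3:49848264	NM_003335.3:c.1232G>A	p.Arg411Lys	-	VUS	NA(a,b)	No		missense
MTC_4	NICN1	chr3:49466617	NM_032316.3:c.56G>A	p.Gly19Asp	-	VUS	NA(a,b)	No		missense
MTC_4	MROH2A	chr2:234712121	NM_001367507.1:c.1736T>C	p.Leu579Pro	-	VUS	NA(a,b)	No		missense
MTC_4	IL16	chr15:81585187	NM_172217.5:c.1712_1718del	p.Glu571Glyfs*7	-	LP	NA(a,b)	No		frameshift
MTC_4	DDX51	chr12:132625554	NM_175066.4:c.1262C>T	p.Pro421Leu	-	VUS	NA(a,b)	No		missense
MTC_4	CCDC134	chr22:42205996	NM_024821.5:c.217del	p.Leu73Serfs*29	-	VUS	NA(a,b)	No		frameshift
MTC_4	ANKRD24	chr19:4217972	NM_133475.1:c.2815G>C	p.Glu939Gln	-	LB	NA(a,b)	No		missense
MTC_4	DNAH11	chr7:21628196	NM_001277115.2:c.1915C>T	p.Gln639*	rs200073714	LP	NA(a)/P(b)	No	0.0002	nonsense
MTC_4	MAPK12	chr22:50699625	NM_002969.6:c.226C>T	p.Arg76Cys	rs138533200	VUS	NA(a,b)	No	0.001	missense
MTC_5	ZNF19	chr16:71509902	NM_006961.4:c.548A>G	p.His183Arg	-	VUS	NA(a,b)	No		missense
MTC_5	USP40	chr2:234394522	NM_001365479.2:c.3299C>A	p.Ala1111Asp	-	VUS	NA(a,b)	No		missense
MTC_5	MSH6	chr2:48030612	NM_000179.3:c.3226C>T	p.Arg1076Cys	rs63750617	P	LP(a,b)	Yes		missense
MTC_5	DGKQ	chr4:955789	NM_001347.4:c.2296C>T	p.Pro766Ser	-	VUS	NA(a,b)	No		missense
MTC_5	COL4A4	chr2:227985771	NM_000092.5:c.286G>A	p.Asp96Asn	rs772710366	VUS	NA(a,b)	No		missense
NMTC_1	FOXM1	chr12:2983469	NM_202002.2:c.176C>A	p.Pro59Gln	-	VUS	NA(a,b)	Yes		missense
NMTC_1	EpCAM	chr2:47613735	NM_002354.3:c.928A>T	p.Arg310Trp	-	LP	NA(a,b)	Yes		missense
NMTC_1	KRT39	chr17:39118666	NM_213656.4:c.858del	p.Trp286Cysfs*6	-	LP	NA(a,b)	No		frameshift
NMTC_1	BTBD16	chr10:124045631	NM_144587.5:c.253G>T	p.Glu85*	-	VUS	NA(a,b)	No		nonsense
NMTC_2	CACNA2D1	chr7:81579757	NM_000722.4:c.3227A>C	p.Gln1076Pro	-	VUS	NA(a,b)	No		missense
NMTC_2	SHISA6	chr17:11461541	NM_207386.4:c.1576C>T	p.His526Tyr	-	VUS	NA(a,b)	No		missense
NMTC_2	AATK	chr17:79096394	NM_001080395.3:c.1342C>T	p.Pro448Ser	rs1256230088	LP	NA(a,b)	No		missense
NMTC_4	JMJD1C	chr10:64967686	NM_032776.3:c.3743A>G	p.Gln1248Arg	-	LP	VUS(a)/LP(b)	No		missense
NMTC_4	AGXT	chr2:241815402	NM_000030.3:c.827T>G	p.Leu276Arg	-	LP	NA(a,b)	No		missense
NMTC_6	HOOK3	chr8:42841854	NM_032410.4:c.1448G>T	p.Gly483Val	-	VUS	NA(a,b)	Yes		missense
NMTC_6	RNF20	chr9:104313988	NM_019592.7:c.1295A>C	p.Lys432Thr	-	VUS	NA(a,b)	No		missense
NMTC_6	GGNBP2	chr17:34913065	NM_024835.5:c.317C>G	p.Ser106Cys	-	LP	NA(a,b)	No		missense
NMTC_7	NKD1	chr16:50667583	NM_033119.5:c.1304T>C	p.Leu435Pro	-	VUS	NA(a,b)	No		missense
NMTC_7	ROBO1	chr3:78763666	NM_002941.4:c.926T>C	p.Ile309Thr	-	VUS	NA(a,b)	No		missense
NMTC_7	MYH10	chr17:8393804	NM_001256012.3:c.4738G>A	p.Glu1580Lys	-	VUS	NA(a,b)	No		missense
NMTC_7	TTC28	chr22:28497190	NM_001145418.1:c.3386C>T	p.Ala1129Val	-	VUS	NA(a,b)	No		missense
NMTC_7	ZZEF1	chr17:3937398	NM_015113.4:c.6495C>A	p.Asn2165Lys	-	VUS	NA(a,b)	No		missense
NMTC_7	CLIC6	chr21:36043050	NM_053277.3:c.1363C>T	p.Leu455Phe	-	LP	NA(a,b)	No		missense
NMTC_7	CSMD2	chr1:34068036	NM_052896.4:c.6649G>A	p.Gly2217Ser	-	LP	NA(a,b)	No		missense
NMTC_7	STK32A	chr5:146741154	NM_001112724.2:c.637G>A	p.Ala213Thr	-	LP	NA(a,b)	No		missense
NMTC_7	TG	chr8:134030213	NM_003235.5:c.6753G>T	p.Trp2251Cys	-	P	NA(a,b)	Yes		missense
NMTC_11	NTRK1	chr1:156843512	NM_002529.3:c.938T>A	p.Leu313Gln	-	VUS	NA(a,b)	Yes		missense
NMTC_11	TNKS	chr8:9578001	NM_003747.3:c.1867C>A	p.Gln623Lys	-	VUS	NA(a,b)	No		missense
NMTC_11	ANKRD35	chr1:145562755	NM_144698.5:c.2443T>C	p.Tyr815His	-	VUS	NA(a,b)	No		missense
NMTC_11	OR51M1	chr11:5410964	NM_001004756.2:c.336G>C	p.Gln112His	-	VUS	NA(a,b)	No		missense
NMTC_11	PPP6R2	chr22:50878140	NM_001242898.2:c.2139G>A	p.Trp713*	-	P	NA(a,b)	No		nonsense
NMTC_12	FNTB	chr14:65519983	NM_001202559.1:c.1166G>A	p.Trp389*	-	P	NA(a,b)	No		nonsense
NMTC_12	ITPR1	chr3:4856888	NM_001168272.2:c.7808C>T	p.Thr2603Met	-	LP	NA(a,b)	No		missense
NMTC_12	PRKG1	chr10:53921669	NM_006258.4:c.1022G>A	p.Gly341Glu	-	VUS	NA(a,b)	No		missense
NMTC_12	DENND2B	chr11:8752138	NM_213618.2:c.697_699del	p.Ser233del	-	VUS	NA(a,b)	No		inframe_indel
NMTC_12	BMP1	chr8:22064964	NM_006129.5:c.2510T>C	p.Met837Thr	-	VUS	NA(a,b)	Yes		missense
NMTC_12	THSD7A	chr7:11521463	NM_015204.3:c.1969G>A	p.Gly657Arg	-	LP	NA(a,b)	No		missense
NMTC_12	INSC	chr11:15243030	NM_001031853.4:c.968G>T	p.Gly323Val	-	LP	NA(a,b)	No		missense
NMTC_12	USH2A	chr1:215848853	NM_206933.4:c.12400G>A	p.Ala4134Thr	-	LP	NA(a,b)	No		missense
NMTC_13	MPPE1	chr18:11886989	NM_023075.6:c.605del	p.Asp202Valfs*20	rs570653089	VUS	NA(a,b)	No		frameshift
NMTC_13	KTI12	chr1:52498811	NM_138417.3:c.623T>A	p.Leu208His	-	VUS	NA(a,b)	No		missense
NMTC_13	BEAN1	chr16:66511533	NM_001178020.3:c.360G>A	p.Trp120*	-	LP	NA(a,b)	No		nonsense
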