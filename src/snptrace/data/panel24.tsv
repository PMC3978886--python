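# Optimised 24-SNP exome sample-identity panel (GRCh37, 1-based positions).
# Dosage convention: dosage counts allele_b (the second-listed allele); the
# af_* columns are HapMap phase 3 frequencies and are taken to refer to
# allele_b. All identity and power statistics are invariant under p <-> 1-p,
# so this choice affects labelling only.
chrom	pos	rsid	gene	allele_a	allele_b	af_CEU	af_CHB	af_JPT	af_YRI
1	179520506	rs1410592	NPHS2	A	C	0.59	0.62	0.54	0.53
1	67861520	rs2229546	IL12RB2	A	G	0.64	0.36	0.44	0.58
2	169789016	rs497692	ABCB11	A	G	0.55	0.65	0.51	0.22
2	227896976	rs10203363	COL4A4	C	T	0.46	0.44	0.36	0.57
3	4403767	rs2819561	SUMF1	A	G	0.56	0.73	0.73	0.72
4	5749904	rs4688963	EVC	A	G	0.33	0.65	0.67	0.52
5	82834630	rs309557	VCAN	A	G	0.49	0.34	0.52	0.50
6	146755140	rs2942	GRM1	C	T	0.54	0.49	0.55	0.47
7	48450157	rs17548783	ABCA13	C	T	0.46	0.72	0.53	0.48
8	94935937	rs4735258	PDP1	C	T	0.40	0.64	0.66	0.46
9	100190780	rs1381532	TDRD7	A	G	0.48	0.59	0.50	0.58
10	100219314	rs10883099	HPSE2	A	G	0.52	0.52	0.53	0.62
11	16133413	rs4617548	SOX6	C	T	0.52	0.65	0.61	0.51
12	993930	rs7300444	WNK1	A	G	0.46	0.55	0.48	0.28
13	39433606	rs9532292	FREM2	A	G	0.29	0.41	0.44	0.54
14	50769717	rs2297995	L2HGDH	A	G	0.55	0.65	0.67	0.59
15	34528948	rs4577050	SLC12A6	C	T	0.68	0.75	0.63	0.32
16	70303580	rs2070203	AARS	A	G	0.53	0.28	0.51	0.49
17	71197748	rs1037256	COG1	C	T	0.50	0.67	0.65	0.56
18	21413869	rs9962023	LAMA3	A	G	0.67	0.81	0.75	0.51
19	10267077	rs2228611	DNMT1	C	T	0.47	0.73	0.56	0.48
20	6100088	rs10373	FERMT1	G	T	0.54	0.31	0.35	0.58
21	44323590	rs4148973	NDUFV3	C	T	0.65	0.33	0.38	0.73
22	21141300	rs4675	SERPIND1	A	C	0.46	0.62	0.51	0.57
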