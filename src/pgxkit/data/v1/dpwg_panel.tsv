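# pgxkit DPWG variant panel
# schema_version=1
# panel_version=DPWG-2020.1
# 45 SNV/indel definitions in 11 pharmacogenes, plus the HLA-B*57:01 tag
# variant (HCP5 rs2395029) and CYP2D6 structural-variant slots. Coordinates
# are 1-based, left-aligned, on both GRCh37 and GRCh38. CYP2B6 *6 and *9
# intentionally share the c.516G>T site (*6 is the combined haplotype label
# reported for unphased single-site evidence; *9 is the single-site allele).
gene	star_label	chrom_37	pos_37	chrom_38	pos_38	ref	alt	hgvs_c	function_class	variant_kind
CYP2B6	*6	19	41512841	19	41006939	G	T	c.516G>T	decreased	snv
CYP2B6	*9	19	41512841	19	41006939	G	T	c.516G>T	decreased	snv
CYP2B6	*4	19	41515263	19	41009361	A	G	c.785A>G	increased	snv
CYP2B6	*5	19	41522715	19	41016813	C	T	c.1459C>T	normal	snv
CYP2B6	*18	19	41515702	19	41009800	T	C	c.983T>C	no_function	snv
CYP2C9	*2	10	96702047	10	94942290	C	T	c.430C>T	decreased	snv
CYP2C9	*3	10	96741053	10	94981296	A	C	c.1075A>C	decreased	snv
CYP2C9	*5	10	96741058	10	94981301	C	G	c.1080C>G	decreased	snv
CYP2C9	*8	10	96702066	10	94942309	G	A	c.449G>A	decreased	snv
CYP2C9	*11	10	96740981	10	94981224	C	T	c.1003C>T	decreased	snv
CYP2C19	*2	10	96541616	10	94781859	G	A	c.681G>A	no_function	snv
CYP2C19	*3	10	96540410	10	94780653	G	A	c.636G>A	no_function	snv
CYP2C19	*4	10	96522463	10	94762706	A	G	c.1A>G	no_function	snv
CYP2C19	*5	10	96612542	10	94852785	C	T	c.1297C>T	no_function	snv
CYP2C19	*6	10	96535173	10	94775416	G	A	c.395G>A	no_function	snv
CYP2C19	*8	10	96535136	10	94775379	T	C	c.358T>C	no_function	snv
CYP2C19	*17	10	96521657	10	94761900	C	T	c.-806C>T	increased	snv
CYP2D6	*3	22	42524243	22	42128241	GA	G	c.775delA	no_function	indel
CYP2D6	*4	22	42524947	22	42128945	C	T	c.506-1G>A	no_function	snv
CYP2D6	*6	22	42525084	22	42129082	GA	G	c.454delT	no_function	indel
CYP2D6	*7	22	42525131	22	42129129	T	G	c.971A>C	no_function	snv
CYP2D6	*8	22	42525134	22	42129132	C	A	c.505G>T	no_function	snv
CYP2D6	*14	22	42525134	22	42129132	C	T	c.505G>A	no_function	snv
CYP2D6	*9	22	42524175	22	42128173	TCTT	T	c.841_843delAAG	decreased	indel
CYP2D6	*10	22	42526694	22	42130692	G	A	c.100C>T	decreased	snv
CYP2D6	*12	22	42526670	22	42130668	C	T	c.124G>A	no_function	snv
CYP2D6	*17	22	42525772	22	42129770	G	A	c.1023C>T	decreased	snv
CYP2D6	*29	22	42523858	22	42127856	C	T	c.1012G>A	decreased	snv
CYP2D6	*41	22	42523805	22	42127803	C	T	c.985+39G>A	decreased	snv
CYP3A5	*3	7	99270539	7	99672916	T	C	c.219-237A>G	no_function	snv
CYP3A5	*6	7	99262835	7	99665212	C	T	c.624G>A	no_function	snv
CYP3A5	*7	7	99250393	7	99652770	T	TA	c.1035_1036insT	no_function	indel
DPYD	*2A	1	97915614	1	97450058	C	T	c.1905+1G>A	no_function	snv
DPYD	*13	1	97981343	1	97515787	A	C	c.1679T>G	no_function	snv
DPYD	c.2846A>T	1	97547947	1	97082391	T	A	c.2846A>T	decreased	snv
DPYD	HapB3	1	98039419	1	97573863	C	T	c.1236G>A	decreased	snv
F5	Leiden	1	169519049	1	169549811	C	T	c.1601G>A	unknown	snv
SLCO1B1	*5	12	21331549	12	21178615	T	C	c.521T>C	decreased	snv
TPMT	*2	6	18143955	6	18143724	C	G	c.238G>C	no_function	snv
TPMT	*3B	6	18139228	6	18138997	C	T	c.460G>A	no_function	snv
TPMT	*3C	6	18130918	6	18130687	T	C	c.719A>G	no_function	snv
TPMT	*4	6	18131012	6	18130781	C	T	c.626-1G>A	no_function	snv
UGT1A1	*28	2	234668879	2	234669485	A	ATA	c.-41_-40dupTA	decreased	indel
UGT1A1	*37	2	234668879	2	234669485	A	ATATA	c.-43_-40dup	decreased	indel
VKORC1	*2	16	31104878	16	31093557	G	A	c.174-136C>T	decreased	snv
HCP5	rs2395029	6	31431780	6	31464003	T	G	n.335T>G	unknown	tag
CYP2D6	*5					.	<DEL>	whole-gene deletion	no_function	sv_slot
CYP2D6	*xN					.	<DUP>	whole-gene duplication	unknown	sv_slot
CYP2D6	*68					.	<HYB>	CYP2D6-CYP2D7 hybrid	no_function	sv_slot
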