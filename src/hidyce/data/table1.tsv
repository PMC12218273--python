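patient	diagnosis	yield_ng	hidy10_mut	hidy10_vaf	ampseq_mut	ampseq_vaf	hidy2_mut	hidy2_vaf	dpcr_mut	dpcr_vaf	ambiguous
1	Adenocarcinoma	1122	G12D	9.4	G12D	12.9	G12D	7.8	G12D	11.4
2	Adenocarcinoma	762	G12V*	27.4	G12V	26.6	G12V*	27.9	G12V	24.4
3	Adenocarcinoma	2388	G12R*	13.3	G12R	13.6	G12R	13.0	G12R	12.3
4	Atypical glands (dysplasia)	21	N/A	-	N/A	-	ND	-	ND	-
5	Adenocarcinoma	466	G12D	9.8	G12D	18.1	G12D	10.8	G12D	15.6
6	Adenocarcinoma	535	G12V*	48.9	G12V	46.2	G12V*	51.0	G12V	40.5
7	Adenocarcinoma	840	G12D	10.1	G12D	12.9	G12D	10.2	G12D	12.7
8	Adenocarcinoma	2940	G12V	5.3	G12V	7.3	G12V	6.7	G12V	4.1
9	Chronic pancreatitis	354	ND	-	ND	-	ND	-	ND	-
10	Duodenum mucosa	27	N/A	-	N/A	-	ND	-	ND	-
11	Adenocarcinoma	226	G12D	39.5	G12D	56.5	G12D*	39.0	G12D	46.3
12	Adenocarcinoma	1638	ND	-	ND	-	ND	-	ND	-
13	Adenocarcinoma	654	G12D	22.2	G12D	31.3	G12D	22.4	G12D	28.0
14	Adenocarcinoma	451	G12V	7.1	G12V	7.6	G12V	6.5	G12V	5.9
15	B cell lymphoma	882	ND	-	ND	-	ND	-	ND	-
16	GIST	346	ND	-	ND	-	ND	-	ND	-
17	GIST	179	ND	-	ND	-	ND	-	ND	-	hidy10,ampseq,hidy2,dpcr
18	Adenocarcinoma	139	G12V*	27.0	G12V	26.8	G12V*	28.1	G12V	23.8
19	GIST	298	ND	-	ND	-	ND	-	ND	-
20	Degeneration tissue	126	ND	-	ND	-	ND	-	ND	-
21	Adenocarcinoma	74	G12V*	34.4	G12V	31.6	G12V*	35.2	G12V	29.4
21	Adenocarcinoma	74	G12R	9.1	G12R	7.9	G12R	10.8	G12R	6.1
22	Adenocarcinoma	798	ND	-	ND	-	ND	-	ND	-	ampseq
23	IOPN (high-grade dysplasia)	1320	ND	-	ND	-	ND	-	ND	-
24	Adenocarcinoma	210	G12V*	32.4	G12V	26.5	G12V*	32.0	G12V	24.7
24	Adenocarcinoma	210	G12R	16.8	G12R	11.7	G12R*	15.3	G12R	10.9
25	Atypical glands (dysplasia)	164	G12R*	12.1	G12R	12.3	G12R	11.0	G12R	9.5
26	Adenocarcinoma	85	G12D	20.5	N/A	-	G12D	22.3	G12D	27.6
27	No evidence of malignancy	22	N/A	-	N/A	-	ND	-	ND	-
28	Insufficient material	25	N/A	-	N/A	-	G12D	5.3	G12D	4.1
29	Insufficient material	39	N/A	-	N/A	-	G12D	3.3	G12D	6.4
30	Insufficient material	36	N/A	-	N/A	-	ND	-	ND	-
31	No evidence of malignancy	432	N/A	-	N/A	-	ND	-	ND	-
32	No evidence of malignancy	179	N/A	-	N/A	-	ND	-	ND	-
33	No evidence of malignancy	726	N/A	-	N/A	-	ND	-	ND	-
34	No evidence of malignancy	180	N/A	-	N/A	-	ND	-	ND	-	hidy2,dpcr
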