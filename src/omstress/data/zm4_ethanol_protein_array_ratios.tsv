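locus_tag	product	proteomics_log2_ratio	proteomics_p_value	array_log2_ratio	array_p_value	significance_index
ZMO1373	TIR protein	3.4	9.50E-06	0.7	5.13E-08	1
ZMO1818	4Fe-4S ferredoxin iron-sulfur binding domain-containing protein	3.2	8.40E-05	-0.3	3.89E-03	1
ZMO0101	putative oxidoreductase	3.2	9.60E-05	1.5	1.66E-31	1
ZMO0405	ATP-dependent Clp protease, ATP-binding subunit ClpA	3.1	2.00E-04	-0.7	5.37E-14	1
ZMO0347	RNA-binding protein Hfq	3.0	3.10E-04	-0.1	5.37E-01	0
ZMO0844	sporulation domain-containing protein	2.9	8.60E-04	0.7	1.05E-06	1
ZMO0896	hypothetical protein	2.9	8.60E-04	0.5	2.40E-12	1
ZMO1041	NUDIX hydrolase	2.8	1.20E-03	-1.2	1.17E-13	1
ZMO0864	cytidine deaminase	2.8	1.60E-03	0.3	1.91E-07	1
ZMO0760	lactoylglutathione lyase	2.8	1.80E-03	0.0	7.08E-01	0
ZMO1466	alpha/beta family hydrolase	2.7	1.10E-05	0.4	1.48E-16	1
ZMO1583	DNA topoisomerase (ATP-hydrolyzing)	2.6	3.40E-03	0.1	1.74E-02	1
ZMO1370	nitrilase/cyanide hydratase and apolipoprotein N-acyltransferase	2.6	4.80E-03	-0.4	7.08E-11	1
ZMO1722	S-(hydroxymethyl)glutathione dehydrogenase/class III alcohol dehydrogenase	2.6	4.80E-03	0.3	6.92E-09	1
ZMO1544	Cobaltochelatase	2.6	4.50E-05	0.5	2.75E-15	1
ZMO1576	putative short-chain dehydrogenase/oxidoreductase	2.5	1.80E-05	-0.2	9.55E-05	1
ZMO1605	pyruvate dehydrogenase subunit beta	2.3	4.10E-06	1.0	5.62E-23	1
ZMO1741	GTP-binding protein LepA	2.0	4.90E-03	0.4	1.62E-08	1
ZMO0811	methionyl-tRNA formyltransferase	1.9	2.20E-03	-0.1	1.91E-02	1
ZMO0734	3'(2'),5'-bisphosphate nucleotidase	1.9	3.80E-04	0.2	1.66E-04	1
ZMO1412	MucR family transcriptional regulator	1.9	2.90E-03	0.9	1.66E-20	1
ZMO1873	glutaredoxin-related protein	1.8	5.40E-03	0.5	3.31E-12	1
ZMO1052	Phosphoribosylaminoimidazolesuccinocarboxamide synthase	1.8	2.30E-03	1.2	1.23E-14	1
ZMO0442	HAD-superfamily hydrolase, subfamily IA, variant 3	1.7	3.20E-03	-0.1	6.31E-01	0
ZMO1334	YceI family protein	1.7	4.30E-05	1.4	3.98E-18	1
ZMO0318	short-chain dehydrogenase/reductase SDR	1.7	2.80E-08	-1.1	8.51E-26	1
ZMO0948	Endopeptidase Clp	1.7	6.30E-08	0.6	3.47E-14	1
ZMO1424	ATPase	1.7	1.20E-11	0.5	3.31E-05	1
ZMO0921	hypothetical protein	1.7	1.20E-03	0.3	1.55E-13	1
ZMO0913	branched-chain amino acid aminotransferase	1.6	5.50E-03	0.7	2.09E-16	1
ZMO0432	arginase family protein	1.5	6.20E-04	0.9	6.17E-26	1
ZMO1684	Phosphoserine transaminase	1.4	1.90E-05	0.8	4.57E-26	1
ZMO0016	GrpE protein	1.3	7.30E-06	0.6	1.17E-12	1
ZMO0855	farnesyl-diphosphate synthase	1.3	2.30E-05	0.3	4.79E-10	1
ZMO1690	heat shock protein DnaJ domain-containing protein	1.2	1.20E-03	-0.8	6.17E-21	1
ZMO1570	Formate C-acetyltransferase	1.2	4.40E-04	0.3	5.89E-04	1
ZMO0593	3-dehydroquinate synthase	1.1	4.70E-04	0.4	6.61E-21	1
ZMO1498	histidine triad (HIT) protein	1.1	2.50E-03	0.0	6.92E-01	0
ZMO0684	CRISPR-associated Csy3 family protein	1.1	1.90E-04	0.8	2.69E-10	1
ZMO1496	Phosphoenolpyruvate carboxylase	1.1	2.30E-05	0.2	2.63E-04	1
ZMO0792	dihydroorotase	1.0	2.80E-03	0.4	1.00E-09	1
ZMO1034	calcium-binding EF-hand-containing protein	1.0	2.20E-06	-0.3	2.69E-02	1
ZMO1294	sugar isomerase (SIS)	-3.5	2.00E-05	-0.1	5.50E-01	0
ZMO1593	peptidase M61 domain-containing protein	-2.9	2.40E-03	-0.1	6.92E-02	0
ZMO0508	GCN5-related N-acetyltransferase	-2.7	4.60E-03	-0.1	1.91E-01	0
ZMO0399	hypothetical protein	-2.1	2.90E-04	-0.1	5.25E-01	0
ZMO0970	putative purine nucleoside permease	-2.1	1.30E-03	0.3	9.55E-06	1
ZMO0610	flagellar basal-body rod FlgF	-1.8	2.00E-04	0.4	1.15E-03	1
ZMO0605	flagellar hook-associated protein FlgK	-1.8	1.10E-03	0.0	8.32E-01	0
ZMO1411	ferric uptake regulator family protein	-1.4	1.90E-03	0.2	2.14E-03	1
ZMO0611	flagellar basal body FlaE domain-containing protein	-1.4	5.10E-18	0.2	1.48E-02	1
ZMO1609	hypothetical protein	-1.3	9.60E-08	0.0	6.61E-01	0
ZMO1542	single-strand binding protein	-1.2	2.60E-04	-0.8	7.76E-08	1
ZMO1712	FKBP-type peptidyl-prolyl cis-trans isomerase 1-like	-1.2	6.70E-05	0.0	7.76E-01	0
ZMO0727	50S ribosomal protein L10	-1.1	3.10E-13	-0.1	8.91E-03	1
ZMO0518	50S ribosomal protein L4	-1.1	2.30E-15	0.3	3.31E-03	1
ZMO1779	hypothetical protein	-1.1	1.60E-17	-0.2	1.35E-05	1
ZMO1490	hypothetical protein	-1.1	4.90E-04	-0.7	1.12E-11	1
ZMO0533	30S ribosomal protein S5	-1.1	2.80E-15	0.8	1.41E-22	1
ZMO1079	50S ribosomal protein L19	-1.1	1.40E-06	-0.3	5.50E-04	1
ZMO0542	50S ribosomal protein L17	-1.0	1.90E-07	0.4	1.15E-02	1
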