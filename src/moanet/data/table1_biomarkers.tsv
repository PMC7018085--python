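rank	uniprot	gene_symbol	gene_name	mean_low	mean_high	strength_printed	p_adjusted	bcp
1	P02675	FGB	Fibrinogen beta chain	-0.576	0.814	0.685	1.297E-03	MD
2	O43639	NCK2	Cytoplasmic protein NCK2	0.620	-0.697	0.657	1.656E-04	MD
3	P54762	EPHB1	Ephrin type-B receptor 1	0.317	-0.677	0.464	3.669E-04	HF&MD
4	Q9Y4H2	IRS2	Insulin receptor substrate 2	0.417	-0.465	0.440	8.181E-04	MD
5	O60674	JAK2	Tyrosine-protein kinase JAK2	-0.747	0.249	0.431	1.656E-04	MD
6	P06241	FYN	Tyrosine-protein kinase Fyn	0.591	-0.236	0.373	2.466E-04	HF&MD
7	P30530	AXL	Tyrosine-protein kinase receptor UFO	0.392	-0.330	0.360	2.111E-04	MD
8	Q02297	NRG1	Pro-neuregulin-1, membrane-bound isoform	0.672	-0.188	0.355	2.111E-04	MD
9	P32004	L1CAM	Neural cell adhesion molecule L1	-0.373	0.309	0.339	1.297E-03	HF&MD
10	Q05586	GRIN1	Glutamate receptor ionotropic, NMDA 1	-0.174	0.620	0.329	1.955E-04	MD
11	P05230	FGF1	Fibroblast growth factor 1	-0.152	0.688	0.323	8.181E-04	HF&MD
12	P18084	ITGB5	Integrin beta-5	0.436	-0.236	0.321	2.111E-04	MD
13	P01583	IL1A	Interleukin-1 alpha	0.174	-0.472	0.287	1.955E-04	MD
14	P10275	AR	Androgen receptor	0.349	-0.201	0.265	8.008E-04	MD
15	P15941	MUC1	Mucin-1 subunit alpha	0.099	-0.652	0.254	6.905E-04	HF&MD
16	O14757	CHEK1	Serine/threonine-protein kinase Chk1	0.436	-0.142	0.248	1.549E-03	MD
17	P15391	CD19	B-lymphocyte antigen CD19	-0.131	0.357	0.216	8.160E-03	MD
18	P61981	YWHAG	14-3-3 protein gamma, N-terminally processed	0.174	-0.236	0.203	2.783E-03	-
19	Q9Y478	PRKAB1	5'-AMP-activated protein kinase subunit beta-1	0.261	-0.142	0.192	5.682E-03	MD
20	P62158	CALM1;CALM2;CALM3	Calmodulin-1	-0.282	0.107	0.174	9.405E-03	MD
21	P06748	NPM1	Nucleophosmin	0.261	-0.107	0.167	3.618E-03	MD
22	O15357	INPPL1	Phosphatidylinositol 3,4,5-trisphosphate 5-phosphatase 2	-0.261	0.094	0.157	3.618E-03	MD
23	P17081	RHOQ	Rho-related GTP-binding protein RhoQ	-0.218	0.094	0.143	9.794E-03	MD
24	P35354	PTGS2	Prostaglandin G/H synthase 2	0.044	-0.472	0.143	3.669E-04	MD
25	P42684	ABL2	Abelson tyrosine-protein kinase 2	-0.218	0.094	0.143	9.794E-03	MD
26	Q15109	AGER	Advanced glycosylation end product-specific receptor	-0.267	0.063	0.130	8.160E-03	-
27	P07585	DCN	Decorin	-0.044	0.236	0.101	5.682E-03	MD
28	P05155	SERPING1	Plasma protease C1 inhibitor	-0.044	0.236	0.101	5.682E-03	MD
29	P05121	SERPINE1	Plasminogen activator inhibitor 1	-0.044	0.236	0.101	5.682E-03	-
30	P14770	GP9	Platelet glycoprotein IX	0.044	-0.236	0.101	5.682E-03	MD
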