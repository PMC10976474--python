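# Differentially expressed cyanophage S-PM2d genes, infection of Synechococcus sp.
# WH7803 under P-deplete vs P-replete conditions, 3 h post-infection.
# misannotated=1 marks CDS judged likely misannotated in the reference genome
# (wrong-strand ORF or tiny ORF inside a tRNA operon).
# FDR/p values kept as decimal strings exactly as printed.
cds_id	accession	product	gene	start	stop	strand	log2fc	pvalue	fdr	presence_pct	misannotated
S-PM2d004	CFW42138.1	Hypothetical protein		1255	1560	+	0.79	3.06E-03	4.36E-02	24.44	0
S-PM2d006	CFW42141.1	Hypothetical protein		1913	2116	+	1.12	6.28E-04	1.60E-02	2.74	0
S-PM2d074	CFW42190.1	Hypothetical protein		14226	14432	-	1.03	1.74E-03	3.06E-02	0.34	1
S-PM2d241	CFW42194.1	Hypothetical protein		14805	15005	+	1.00	1.51E-03	2.88E-02	0.17	0
S-PM2d115	CFW42285.1	Hypothetical protein		75481	75699	+	0.63	4.18E-03	5.03E-02	13.50	0
S-PM2d118	CFW42290.1	Recombination endonuclease subunit	gp46	77014	78744	+	0.98	1.61E-04	6.15E-03	74.70	0
S-PM2d131	CFW42313.1	Hypothetical protein		87134	87601	+	1.12	5.76E-05	4.40E-03	9.40	0
S-PM2d132	CFW42314.1	Hypothetical protein		87598	87849	+	1.04	1.18E-04	5.86E-03	9.23	0
S-PM2d133	CFW42316.1	DNA polymerase	gp43	87849	90341	+	0.63	2.62E-03	3.99E-02	84.44	0
S-PM2d134	CFW42318.1	UvsX RecA-like recombination protein	uvsX	90352	91383	+	0.84	1.21E-03	2.78E-02	75.04	0
S-PM2d135	CFW42319.1	DNA primase-helicase	gp41	91343	92755	+	0.67	3.24E-03	4.36E-02	74.53	0
S-PM2d136	CFW42320.1	Pyrophosphatase	mazG	92757	93164	+	1.33	1.11E-05	2.11E-03	74.53	0
S-PM2d169	CFW42374.1	Hypothetical protein		114418	114768	+	1.42	1.84E-05	2.11E-03	26.67	0
S-PM2d172	CFW42378.1	High-light inducible protein	hli2	115295	115414	+	0.76	1.41E-03	2.88E-02	50.94	0
S-PM2d190	CFW42403.1	Hypothetical protein		132902	133072	+	0.87	3.10E-04	1.01E-02	0.85	0
S-PM2d250	CFW42449.1	Putative ATPase		155233	155376	+	0.71	3.19E-02	1.61E-01	0.17	1
S-PM2d216	CFW42450.1	Hypothetical protein		155436	155594	+	0.91	2.01E-03	3.29E-02	0.17	1
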