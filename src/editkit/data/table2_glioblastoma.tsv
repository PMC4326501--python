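chrom	mirna	adar2	adar2_ea	siadar2	log2_adar2_vs_ea	log2_siadar2_vs_adar2	cancer
Chr9	hsa-let-7d	0	18,813	13,703	-14.1995	13.7423	yes
Chr2	hsa-miR-10b	0	11,101	559	-13.4385	9.1293	yes
Chr7	hsa-miR-335*	5,296	14,463	5,463	-1.4492	0.0448	no
Chr5	hsa-miR-143	61,575	159,453	81,440	-1.3727	0.4034	yes
Chr7	hsa-miR-25	29,424	58,238	35,063	-0.9849	0.2529	yes
Chr19	hsa-let-7e	30,846	56,890	36,482	-0.8831	0.2421	yes
Chr7	hsa-miR-29a	33,734	59,096	49,119	-0.8088	0.5421	yes
Chr17	hsa-miR-21	919,239	1,506,954	1,384,694	-0.7131	0.1581	yes
Chr17	hsa-miR-21*	53,970	84,276	106,392	-0.6430	0.9791	yes
Chr3	hsa-miR-138-1*	4,460	6,714	5,063	-0.5900	0.1829	yes
ChrX	hsa-miR-222	277,271	410,972	348,219	-0.5677	0.3287	yes
Chr19	hsa-miR-769	6,339	9,225	6,433	-0.5412	0.0212	no
Chr6	hsa-miR-30a*	9,650	13,716	13,235	-0.5072	0.4619	yes
Chr10	hsa-miR-146b	12,692	6,639	10,948	0.9348	-0.2132	yes
Chr2	hsa-miR-548s	11,559	822	22	0.3269	-8.3083	no
Chr19	hsa-miR-520c	14,093	0	0	13.7828	-13.7828	yes
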