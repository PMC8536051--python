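rsid	chrom	position	gene	function	ref_allele	alt_allele	GLOBAL_eaf	AMR_eaf	AMR_log10p	AFR_eaf	AFR_log10p	EAS_eaf	EAS_log10p	SAS_eaf	SAS_log10p	EUR_eaf	EUR_log10p	KOR_eaf	KOR_log10p
rs2131925	chr1	63025942	DOCK7	intron_variant	G	T	0.56	0.61	1.61	0.31	-58.18	0.77	35.67	0.53	-0.97	0.69	13.25	0.785	102.29
rs10908454	chr1	155066416	EFNA3-AL691442.1	TF_binding_site_variant	G	A	0.55	0.64	4.64	0.31	-53.75	0.91	116.71	0.51	-1.48	0.48	-3.99	0.919	312.61
rs11264322	chr1	155087933	EFNA3-AL691442.1	intergenic_variant	G	A	0.54	0.61	2.91	0.3	-53.97	0.91	122.04	0.5	-1.51	0.45	-6.28	0.919	312.61
rs11264360	chr1	155284586	FDPS	intron_variant	T	A	0.35	0.3	-1.79	0.2	-25.83	0.7	91.61	0.3	-2.46	0.27	-5.79	0.638	149.83
rs11264361	chr1	155289545	FDPS, RUSC1-AS1	non_coding_transcript_exon_variant	T	G	0.35	0.3	-1.79	0.21	-22.25	0.71	96.83	0.31	-1.66	0.26	-7.22	0.801	312.61
rs10908465	chr1	155389688	ASH1L	intron_variant	C	T	0.34	0.31	-0.75	0.14	-48.92	0.71	102.27	0.31	-1.04	0.28	-3.40	0.811	312.61
rs562338	chr2	21288321	APOB-AC010872.2	intergenic_variant	A	G	0.73	0.82	6.07	0.35	-138.10	0.98	91.24	0.87	21.07	0.8	5.29	0.995	311.61
rs541041	chr2	21294975	APOB-AC010872.2	intergenic_variant	G	A	0.75	0.82	3.96	0.4	-119.94	0.99	93.79	0.88	19.24	0.8	3.04	0.995	282.11
rs6782190	chr3	85639672	CADM2	intron_variant	G	A	0.65	0.73	4.16	0.37	-73.11	0.94	91.71	0.64	-0.23	0.65	0.00	0.936	231.64
rs200641845	chr4	72620895	GC	intron_variant	T	A	0.42	0.43	0.14	0.34	-6.80	0.45	1.03	0.47	2.24	0.45	1.02	0.080	-285.57
rs1607741	chr4	72719033	AC068721.1-NPFFR2	intergenic_variant	G	C	0.58	0.72	11.29	0.49	-8.10	0.42	-19.40	0.61	0.98	0.73	18.02	0.338	-106.15
rs1614377	chr4	100279332	ADH1B-ADH7	intergenic_variant	G	A	0.15	0.17	0.61	0.095	-6.69	0.026	-33.64	0.18	1.55	0.31	28.74	0.012	-125.88
rs12642639	chr4	100301241	ADH1B-ADH7	intergenic_variant	C	A	0.38	0.14	-37.19	0.34	-2.07	0.65	54.04	0.51	12.56	0.21	-24.90	0.825	312.61
rs10070734	chr5	87940026	LINC00461	intron_variant	T	C	0.5	0.46	-1.12	0.46	-1.92	0.25	-48.15	0.61	9.11	0.71	33.25	0.217	-155.96
rs31612	chr5	108996643	KRT18P42-AC012603.1	intergenic_variant	T	C	0.32	0.28	-1.27	0.12	-51.58	0.61	63.57	0.46	15.17	0.18	-18.77	0.654	201.59
rs804280	chr8	11612698	GATA4	intron_variant	C	A	0.73	0.69	-1.31	0.6	-18.48	0.99	103.54	0.87	21.07	0.56	-24.11	0.975	231.56
rs10818769	chr9	125719923	RABGAP1	intron_variant	C	G	0.49	0.58	4.58	0.071	-197.61	0.31	-24.91	0.83	89.25	0.85	104.26	0.260	-100.85
rs9409266	chr9	125745042	RABGAP1	intron_variant	G	A	0.49	0.58	4.58	0.07	-198.46	0.31	-24.91	0.83	89.25	0.85	104.26	0.260	-101.09
rs10887718	chr10	82042624	MAT1A	intron_variant	C	T	0.66	0.67	0.16	0.41	-58.77	0.97	114.96	0.76	8.79	0.54	-11.52	0.979	312.61
rs12411742	chr10	82042782	MAT1A	intron_variant	G	A	0.66	0.67	0.16	0.41	-58.77	0.97	114.96	0.76	8.79	0.54	-11.52	0.979	312.61
rs1620013	chr11	71089210	SHANK2-AP002387.1	intergenic_variant	C	T	0.48	0.45	-0.72	0.45	-1.21	0.66	24.42	0.53	2.16	0.3	-24.67	0.717	104.75
rs1396206	chr12	24576859	SOX5	intron_variant	A	T	0.7	0.67	-0.78	0.67	-1.37	0.97	94.88	0.61	-6.85	0.58	-12.07	0.967	245.87
rs12881545	chr14	101176212	AL132711.1-DLK1	TF_binding_site_variant	G	C	0.26	0.38	9.25	0.029	-97.30	0.0069	-103.17	0.35	7.30	0.65	116.98	0.000	-286.57
rs17765311	chr15	63789952	AC007950.1-AC007950.2	regulatory_region_variant	A	C	0.16	0.2	1.80	0.016	-58.56	0.001	-65.52	0.26	11.55	0.4	57.06	0.003	-174.20
rs55829990	chr15	63790642	AC007950.1-AC007950.2	intergenic_variant	T	C	0.16	0.2	1.80	0.019	-54.99	0.002	-63.59	0.26	11.55	0.4	57.06	0.003	-174.20
rs28607847	chr15	66284913	MEGF11	intron_variant	G	A	0.38	0.22	-15.36	0.36	-0.69	0.62	42.80	0.38	0.00	0.29	-6.89	0.668	149.95
rs3814995	chr19	36342212	NPHS1	missense_variant	C	T	0.29	0.34	1.85	0.056	-84.87	0.6	74.07	0.24	-2.58	0.31	0.62	0.587	162.75
rs6123359	chr20	52714706	BCAS1-CYP24A1	regulatory_region_variant	A	G	0.21	0.1	-11.63	0.083	-28.70	0.55	96.31	0.22	0.27	0.11	-13.14	0.511	180.25
rs960596	chr22	41393520	RBX1-AL080243.3	intergenic_variant	C	T	0.27	0.2	-3.71	0.026	-107.11	0.43	21.65	0.38	10.42	0.35	5.99	0.508	108.51
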