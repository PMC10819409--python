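clone_id	contig	start	end	gene	variant_type	effect
HNDS0068-01 #B CC3	chr1	181548260	181548260	CACNA1E	SNP	nonsynonymous
HNDS0068-01 #B CC3	chr3	126915614	126915614	C3ORF56	SNP	nonsynonymous
HNDS0068-01 #B CC3	chr22	26168388	26168388	MYO18B	SNP	nonsynonymous
HNDS0078-01 #D CNC2	chr16	6367034	6367034	RBFOX1	SNP	nonsynonymous
HNDS0078-01 #D CC18	chr8	105368407	105368407	DCSTAMP	SNP	nonsynonymous
HNDS0072-01 #C CNC87	chr7	6692698	6692698	ZNF316	SNP	nonsynonymous
HNDS0072-01 #C CC20	chr17	36486618	36486618	GPR179	SNP	nonsynonymous
HNDS0072-01 #C CC80	chr2	21365297	21365297	TDRD15	SNP	nonsynonymous
HNDS0072-01 #C CC80	chr16	15878562	15878562	MYH11	SNP	nonsynonymous
31 CC-het	chr8	1616677	1616677	DLGAP2	SNP	nonsynonymous
31 CC-het	chr15	45562441	45562441	SLC28A	SNP	nonsynonymous
31 CC-hom	chr1	184692924	184692924	EDEM3	SNP	nonsynonymous
31 CC-hom	chr2	170850922	170850922	URB3	SNP	nonsynonymous
31 CC-hom	chr5	140589980	140589980	PCDHB12	SNP	nonsynonymous
31 CC-hom	chr9	80412511	80412511	GNAQ	deletion	.
31 CC-hom	chr11	64679322	64679322	ATG2A	SNP	nonsynonymous
31 CC-hom	chr15	42492130	42492130	VPS39	SNP	nonsynonymous
31 CC-hom	chr16	560714	560714	RAB11FIP3	SNP	nonsynonymous
31 CC-hom	chr16	30001071	30001071	TAOK2	SNP	nonsynonymous
1-1134-003_CNC5	chr4	964783	964783	DGKQ	SNP	nonsynonymous
1-1217-003_CNC36	chr5	148709327	148709327	AFAP1L1	SNP	nonsynonymous
1-1006-003_CC9	chr14	42356229	42356230	LRFN5	MNP	nonframeshift_substitution
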