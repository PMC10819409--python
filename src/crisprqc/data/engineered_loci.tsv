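clone_id	gene	edit_locus	cas_label	delivery	target_contig	target_start	target_end
HNDS0068-01 #B CNC14	KCNQ2	chr20:62071001-62071003	Cas9	RNP	chr20	62071008	62071027
HNDS0068-01 #B CC3	KCNQ2	chr20:62071001-62071003	Cas9	RNP	chr20	62071008	62071027
HNDS0078-01 #D CNC2	KCNQ2	chr20:62073808	Cas9	RNP	chr20	62073830	62073848
HNDS0078-01 #D CC8	KCNQ2	chr20:62073808	Cas9	RNP	chr20	62073830	62073848
HNDS0078-01 #D CC18	KCNQ2	chr20:62073808	Cas9	RNP	chr20	62073830	62073848
HNDS0072-01 #C CNC87	KCNQ2	chr20:62071057	Cas9	RNP	chr20	62071037	62071056
HNDS0072-01 #C CC80	KCNQ2	chr20:62071057	Cas9	RNP	chr20	62071037	62071056
HNDS0072-01 #C CC20	KCNQ2	chr20:62071057	Cas9	RNP	chr20	62071037	62071056
31 CC-het	GNAQ	chr9:80412493	Cas9	plasmid	chr9	80412499	80412518
31 CC-hom	GNAQ	chr9:80412493	Cas9	plasmid	chr9	80412499	80412518
1-1134-003_CNC5	ASH1L	chr1:155451888	Cas12a	RNP	chr1	155451881	155451901
1-1134-003_CC10	ASH1L	chr1:155451888	Cas12a	RNP	chr1	155451881	155451901
1-1217-003_CNC36	ASH1L	chr1:155447758	Cas9	RNP	chr1	155447747	155447768
1-1217-003_CC37	ASH1L	chr1:155447758	Cas9	RNP	chr1	155447747	155447768
1-1006-003_CNC35	ASH1L	chr1:155450703	Cas12a	RNP	chr1	155450703	155450723
1-1006-003_CC9	ASH1L	chr1:155450703	Cas12a	RNP	chr1	155450703	155450723
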