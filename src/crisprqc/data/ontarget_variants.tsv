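clone_id	contig	start	end	gene	variant_type	effect	intended
HNDS0068-01 #B CC3	chr20	62071011	62071011	KCNQ2	SNP	synonymous	yes
HNDS0078-01 #D CC8	chr20	62073825	62073825	KCNQ2	SNP	synonymous	yes
HNDS0078-01 #D CC8	chr20	62073828	62073828	KCNQ2	SNP	synonymous	yes
HNDS0078-01 #D CC8	chr20	62073873	62073875	KCNQ2	MNP	nonframeshift_substitution	no
HNDS0078-01 #D CC18	chr20	62073825	62073825	KCNQ2	SNP	synonymous	yes
HNDS0078-01 #D CC18	chr20	62073828	62073828	KCNQ2	SNP	synonymous	yes
HNDS0072-01 #C CC80	chr20	62071055	62071055	KCNQ2	SNP	synonymous	yes
HNDS0072-01 #C CC80	chr20	62071037	62071037	KCNQ2	insertion	frameshift_insertion	no
HNDS0072-01 #C CC20	chr20	62071055	62071055	KCNQ2	SNP	synonymous	yes
31 CC-het	chr9	80412493	80412493	GNAQ	SNP	nonsynonymous	yes
31 CC-hom	chr9	80412493	80412493	GNAQ	SNP	nonsynonymous	yes
1-1134-003_CC10	chr1	155451881	155451881	ASH1L	SNP	synonymous	yes
1-1134-003_CC10	chr1	155451898	155451898	ASH1L	SNP	synonymous	yes
1-1134-003_CC10	chr1	155451904	155451904	ASH1L	SNP	synonymous	yes
1-1217-003_CC37	chr1	155447750	155447750	ASH1L	SNP	synonymous	yes
1-1217-003_CC37	chr1	155447753	155447753	ASH1L	SNP	synonymous	yes
1-1217-003_CC37	chr1	155447771	155447771	ASH1L	SNP	synonymous	yes
1-1006-003_CC9	chr1	155450705	155450705	ASH1L	SNP	synonymous	yes
1-1006-003_CC9	chr1	155450708	155450708	ASH1L	SNP	synonymous	yes
1-1006-003_CC9	chr1	155450723	155450723	ASH1L	SNP	synonymous	yes
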