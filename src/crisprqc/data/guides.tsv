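guide_id	gene	protospacer	pam	pam_side	cas_label
kcnq2-g1	KCNQ2	ACCCCCAGACCTGGAACGGC	AGG	three_prime	Cas9
kcnq2-g2	KCNQ2	TCTCATCCTGGCCTCGTTCC	TGG	three_prime	Cas9
kcnq2-g3	KCNQ2	GCTGACCACCATTGGCTACG	GGG	three_prime	Cas9
ash1l-g1	ASH1L	ATCAGGAAAGCAGTGTTGGC	TTTG	five_prime	Cas12a
ash1l-g2	ASH1L	GTCCTGTGCAGAAGAGTCCA	GGG	three_prime	Cas9
ash1l-g3	ASH1L	CAAGGGAAGAGCTTATTCTT	TTTC	five_prime	Cas12a
gnaq-g1	GNAQ	CTAAGCACATCTTGTTGCGT	AGG	three_prime	Cas9
hprt1-g1	HPRT1	GATGATCTCTCAACTTTAAC	TGG	three_prime	Cas9
hprt1-g2	HPRT1	TGTAGGACTGAACGTCTTGCTCG	TTTC	five_prime	Cas12a
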