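clone_id	coverage	n_unique_snv	n_unique_indel	n_unique_sv
HNDS0068-01 #B CNC14	42.5	202	40	0
HNDS0068-01 #B CC3	37.1	229	24	0
HNDS0078-01 #D CNC2	49.2	217	49	0
HNDS0078-01 #D CC8	49.6	242	40	0
HNDS0078-01 #D CC18	39.9	194	34	0
HNDS0072-01 #C CNC87	36.3	363	36	0
HNDS0072-01 #C CC80	43.8	327	44	1
HNDS0072-01 #C CC20	41.8	343	46	0
31 CC-het	42.8	432	77	0
31 CC-hom	33.4	792	73	1
1-1134-003_CNC5	45.4	190	48	0
1-1134-003_CC10	45.2	220	46	0
1-1217-003_CNC36	32.2	265	60	0
1-1217-003_CC37	39.2	260	64	0
1-1006-003_CNC35	39.4	268	64	0
1-1006-003_CC9	44.3	234	71	0
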