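clone_id	contig	start	end
HNDS0072-01 #C CC80	chr20	62068445	62070301
31 CC-hom	chr9	80412512	80412841
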