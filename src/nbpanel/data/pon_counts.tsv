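chrom	pos	ref	alt	count
chr3	11280090	A	T	96
chr17	7192100	G	T	20
chr17	41199350	C	G	15
chr11	535300	T	G	1
chr2	29418700	G	T	2
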