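chrom	pos	ref	alt	af
chr3	11274072	G	C	0.620000
chr3	11277100	C	T	0.020000
chr17	41196400	A	G	0.050000
chr18	9329050	T	C	0.012000
chr11	532300	G	A	0.001000
chr2	29415700	C	A	0.000500
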