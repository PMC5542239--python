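gene	c_change	protein_change	effect
ALK	c.3824G>A	R1275Q	missense
ALK	c.3520T>A	F1174I	missense
ALK	c.3522C>A	F1174L	missense
ALK	c.3574C>G	R1192G	missense
ALK	c.3734T>G	F1245C	missense
HRAS	c.182A>G	Q61R	missense
MET	c.3028+2T>C	exon14_skip	splice
ATRX	c.5962G>T	A1988S	missense
ATRX	c.6566T>C	V2189A	missense
ATRX	c.1492C>G	R498G	missense
BRCA1	c.5266dupC	Q1756fs	frameshift
BRCA1	c.68_69delAG	E23fs	frameshift
BRCA1	c.5251C>T	R1751*	nonsense
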