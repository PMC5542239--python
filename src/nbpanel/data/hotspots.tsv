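gene	protein_change
ALK	R1275Q
ALK	F1174I
ALK	F1174L
ALK	R1192G
ALK	F1245C
ALK	F1245V
HRAS	Q61R
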