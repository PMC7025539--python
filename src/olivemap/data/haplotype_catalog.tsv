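haplotype	accession	dominant	36	47	63	77	103	106	142	155	171	173	198	217	218	283
S-A	MN256463	yes	T	G	T	T	T	TT	T	G	G	T	C	T	T	T
S-B	MN256465	yes	T	G	T	C	C	-	T	G	G	T	C	C	-	T
s-a	MN256464	no	T	G	T	T	T	TT	C	A	A	C	T	T	T	C
s-b	MN256465	no	A	T	G	C	C	TT	T	G	G	T	C	T	T	T
s-c	MN256466	no	T	G	G	C	C	TT	T	G	G	T	C	T	T	T
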