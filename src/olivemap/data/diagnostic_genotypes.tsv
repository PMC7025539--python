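group	combination	raw_diagnostic	geno63	geno283
G1	S-B/-	TT/-	TT	TT
G1	S-A/-	TT/-	TT	TT
G1	S-A/s-a	TT/TC	TT	TC
G1	S-A/s-b	TG/TT	TG	TT
G1	S-A/s-c	TG/TT	TG	TT
G2	s-a/s-a	TT/CC	TT	CC
G2	s-a/s-b	TG/CT	TG	CT
G2	s-a/s-c	TG/CT	TG	CT
G2	s-b/s-b	GG/TT	GG	TT
G2	s-b/s-c	GG/TT	GG	TT
G2	s-c/s-c	GG/TT	GG	TT
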