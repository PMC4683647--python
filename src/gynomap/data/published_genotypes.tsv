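id	LG4	LG6	LGx
OR-MRD93	mfmf	Rr	TT
OR-MRD61	mfmf	RR	TT
OR-MRD45	mfmf	RR	Tt
OR-MRD30	MSmf	RR	TT
OR-MRD27	MSmf	RR	TT
OR-MRD90	MSmf	RR	TT
NM-LNF23	mfmf	Rr	TT
NM-LNF25	mfmf	Rr	TT
NM-LNF14	mfmf	Rr	Tt
NM-LNF2	mfmf	rr	TT
NM-LNF4	mfmf	rr	TT
NM-LNF26	mfmf	rr	TT
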