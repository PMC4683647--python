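id	population	sex	mitotype
OR-MRD93	OR-MRD	H	B
OR-MRD61	OR-MRD	H	C
OR-MRD45	OR-MRD	H	C
OR-MRD30	OR-MRD	F	C
OR-MRD27	OR-MRD	F	C
OR-MRD90	OR-MRD	F	C
NM-LNF23	NM-LNF	H	F
NM-LNF25	NM-LNF	H	F
NM-LNF14	NM-LNF	H	F
NM-LNF2	NM-LNF	F	F
NM-LNF4	NM-LNF	F	F
NM-LNF26	NM-LNF	F	F
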