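locus	HLA-C
	Cw*0210	Cw*0302	Cw*0304	Cw*0401	Cw*0602	Cw*0701	Cw*0702	Cw*0704	Cw*0802	Cw*1601	Cw*1701	Cw*1801
HLA-C 001	.	.	.	.	X	.	.	.	.	.	.	X
HLA-C 002	.	.	.	.	.	X	X	X	.	.	.	.
HLA-C 003	.	.	.	X	.	.	.	.	.	.	.	.
HLA-C 004	.	X	X	.	.	X	X	X	X	X	.	.
HLA-C 005	X	.	.	.	X	.	.	.	.	.	.	.
HLA-C 006	.	.	.	.	X	X	X	.	.	X	.	.
HLA-C 007	.	.	.	.	.	.	.	.	.	.	X	.
HLA-C 008	.	.	X	.	.	.	.	.	.	.	.	.
HLA-C 009	.	.	.	.	.	.	.	X	.	.	.	.
HLA-C 010	.	.	.	.	.	.	X	.	.	.	.	.
HLA-C 011	.	.	.	.	.	.	.	.	.	X	.	.
HLA-C 012	.	.	.	X	.	.	.	.	X	.	.	X
HLA-C 013	X	.	.	.	.	.	.	.	.	.	.	.
HLA-C 014	.	X	.	.	.	.	.	.	.	.	.	.
HLA-C 015	.	X	X	.	.	X	.	.	.	.	X	.
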