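locus	HLA-A
	A*0101	A*0201	A*0202	A*0205	A*0301	A*2301	A*2902	A*3001	A*3002	A*3402	A*3601	A*6601	A*6802	A*7401
HLA-A 001	.	.	.	.	.	.	X	.	.	.	.	.	.	.
HLA-A 002	.	.	.	X	.	.	.	.	.	X	.	X	X	.
HLA-A 003	.	.	.	X	.	.	.	.	.	.	.	.	.	.
HLA-A 004	.	.	.	.	.	.	.	.	.	X	.	X	X	.
HLA-A 005	.	.	.	.	.	X	.	.	.	.	.	.	.	.
HLA-A 006	.	.	.	.	.	.	.	.	X	.	.	.	.	.
HLA-A 007	X	.	.	.	.	.	.	.	.	.	X	.	.	.
HLA-A 008	.	X	X	.	.	.	.	.	.	.	.	.	.	.
HLA-A 009	.	.	.	.	X	.	.	.	.	.	.	.	.	X
HLA-A 010	.	X	X	.	X	.	.	.	.	.	.	.	.	X
HLA-A 011	.	X	X	X	.	.	.	.	.	.	.	.	X	.
HLA-A 012	X	.	.	.	.	.	.	.	.	.	.	X	.	.
HLA-A 013	.	.	.	.	.	.	X	.	.	.	.	.	.	X
HLA-A 014	.	.	.	.	.	.	.	.	.	.	X	.	.	.
HLA-A 015	.	.	.	.	X	.	.	.	.	X	.	.	.	.
HLA-A 016	.	X	.	.	X	X	.	X	X	X	.	.	.	.
HLA-A 017	.	.	X	X	.	.	.	.	.	.	.	.	.	.
HLA-A 018	X	.	X	X	.	.	.	.	.	.	X	X	X	.
HLA-A 019	.	.	.	.	.	.	.	X	.	.	.	.	.	.
HLA-A 020	.	.	.	.	.	.	.	X	X	.	.	.	.	.
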