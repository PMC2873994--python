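locus	HLA-A
reference	NC_000006.10 30018310-30021633

[primers]
A226F01	GGCTCYCACTCCATGAGGTATTTC	forward	203-226
A228F01	GGCTCYCACTCCATGAGGTATTTCAC	forward	203-228
A228F02	GGCTCYCACTCCATGAGGTATTTCTA	forward	203-228
A228F03	GGCTCYCACTCCATGAGGTATTTCTC	forward	203-228
A228F04	GGCTCYCACTCCATGAGGTATTTCT[C]	forward	203-228
A228F05	GGCTCYCACTCCATGAGGTATTTCTT	forward	203-228
A228F06	GGCTCYCACTCCATGAGGTATTTCT[T]	forward	203-228
A400R01	TCTGTGASTGGGCCTTCACT	reverse	400-419
A400R02	TCTGTGASTGGGCCTTCAT[A]	reverse	400-419
A400R03	TCTGTGASTGGGCCTTCACA	reverse	400-419
A400R04	TCTGTGASTGGGCCTTCAC[A]	reverse	400-419
A402R01	TCTGTGASTGGGCCTTCA	reverse	402-419
A429R01	GCAGGGTCCCCAGGTTCT	reverse	429-446
A429R02	CGCGATCCGCAGGTTCT	reverse	429-444
A429R03	CAGGGTCCCCAGGTTCG	reverse	429-445
A429R04	CAGGGTCCCCAGGTCCA	reverse	429-445
A734F01	NGTTCTCACACCVTCCAGAGG	forward	714-734
A756F01	GCTGCGACGTGGGGT	forward	742-756
A818F01	GGCAAGGATTACATCGCC	forward	801-818
A819F01	GGCAAGGATTACATCGCCC	forward	801-819
A819F02	GGCAAGGATTACATCGCC[C]	forward	801-819
A819F03	GGCAAGGATTACATCGCC[T]	forward	801-819
A898R01	RCTCTCMRCTGCTCCGCC[T]	reverse	898-916
A898R02	RCTCTCMRCTGCTCCGCCA	reverse	898-916
A910F01	TCCATTCGGCGGAGCAACG	forward	892-910
A910R02	GCCCTCCAGGTAGRCTCTC[C]	reverse	910-929
A910R03	GCCCTCCAGGTAGGCTCTC[A]	reverse	910-929
A930R01	GAGCCMSTCCACGCACGT	reverse	930-947
A930R02	GAGCCMSTCCACGCACG[T]	reverse	930-947
A930R03	AGCCMSTCCACGCACC[G]	reverse	930-946
A932R01	GAGCCMSTCCACGCAC	reverse	932-947

[probes]
A278P01	FAM	BHQ1	CGCACAAACTGCATGTCGTCCACGTAGCC	278-306
A846P01	TET	BHQ1	TCTGAGCCGCCATGTCCGCCGC	846-867
A921P01	TET	BHQ1	CTGGAGGGCTGCTGCGTGGAGTGG	921-944

[reactions]
HLA-A 001	A228F01	A429R03	A278P01	A818F01	A932R01	A846P01	A*2902
HLA-A 002	A228F02	A429R04	A278P01	A818F01	A932R01	A846P01	A*0205,A*3402,A*6601,A*6802
HLA-A 003	A228F02	A400R01	A278P01	A818F01	A932R01	A846P01	A*0205
HLA-A 004	A228F02	A400R03	A278P01	A818F01	A932R01	A846P01	A*3402,A*6601,A*6802
HLA-A 005	A228F04	A429R02	A278P01	A818F01	A932R01	A846P01	A*2301
HLA-A 006	A228F03	A429R01	A278P01	A818F01	A932R01	A846P01	A*3002
HLA-A 007	A228F05	A400R02	A278P01	A818F01	A932R01	A846P01	A*0101,A*3601
HLA-A 008	A228F06	A400R01	A278P01	A818F01	A932R01	A846P01	A*0201,A*0202
HLA-A 009	A228F06	A400R04	A278P01	A818F01	A932R01	A846P01	A*0301,A*7401
HLA-A 010	A228F06	A429R04	A278P01	A818F01	A932R01	A846P01	A*0201,A*0202,A*0301,A*7401
HLA-A 011	A734F01	A898R02	A846P01	A226F01	A402R01	A278P01	A*0201,A*0202,A*0205,A*6802
HLA-A 012	A819F02	A930R03	A846P01	A226F01	A402R01	A278P01	A*0101,A*6601
HLA-A 013	A819F03	A930R01	A846P01	A226F01	A402R01	A278P01	A*2902,A*7401
HLA-A 014	A910F01	A930R02	A921P01	A226F01	A402R01	A278P01	A*3601
HLA-A 015	A756F01	A898R01	A846P01	A226F01	A402R01	A278P01	A*0301,A*3402
HLA-A 016	A819F02	A910R03	A846P01	A226F01	A402R01	A278P01	A*0201,A*0301,A*2301,A*3001,A*3002,A*3402
HLA-A 017	A756F01	A910R02	A846P01	A226F01	A402R01	A278P01	A*0202,A*0205
HLA-A 018	A819F01	A910R02	A846P01	A226F01	A402R01	A278P01	A*0101,A*0202,A*0205,A*3601,A*6601,A*6802
HLA-A 019	A228F04	A429R04	A278P01	A818F01	A932R01	A846P01	A*3001
HLA-A 020	A228F04	A400R04	A278P01	A818F01	A932R01	A846P01	A*3001,A*3002
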