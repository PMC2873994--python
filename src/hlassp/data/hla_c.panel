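locus	HLA-C
reference	NC_000006.10 31347834-31344508

[primers]
C235F01	CTCCCACTCCATGAGGTATTTCG[A]	forward	212-235
C242F01	CCATGAGGTATTTCTYCACATCC	forward	220-242
C255F01	TGTGTCCCGGCCCA	forward	242-255
C255F02	YGTGTCCCGGCCCG	forward	242-255
C329F01	GTTCGACAGCGACGCC	forward	314-329
C426R01	GCAGGTTCACTCGGTCAGT	reverse	426-444
C427R01	CGCAGGYTCACTCGGTCAG	reverse	427-445
C439R01	GCAGTTTCCGCAGGT	reverse	439-453
C439R02	GCAGGTTCCGCAGG[C]	reverse	439-453
C755F01	TCACCCTCCAGAGGATGTA	forward	737-755
C755F02	TCACCCTCCAGAGGATGTC	forward	737-755
C798F01	CCTCCTCCGCGGGTAT	forward	783-798
C799F01	CTCCTCCGCGGGTATG	forward	784-799
C806F01	CCGCGGGTATGACCAGT[A]	forward	789-806
C806F02	CCGCGGGTATGACCAGTC	forward	789-806
C806F03	CCGCGGGTATGACCAGT[C]	forward	789-806
C806F04	CCGCGGGTATAACCAGTT	forward	789-806
C925R01	CTCCAGGTAGGCTCTCTG	reverse	925-942
C925R02	CTCCAGGTAGGCTCTCCG	reverse	925-942
C925R03	CTCCAGGTAGGCTCTCAG	reverse	925-942
C925R05	CTCCAGGTAGGCTCTGTC	reverse	925-942
C925R06	CTCCAGGTAGGCTCTCCA	reverse	925-942
C946R01	AGCCACTCCACGCACG[T]	reverse	946-962
C946R02	AGCCACTCCACGCACAG	reverse	946-962
C946R03	AGCCACTCCACGCACT[C]	reverse	946-962
C948R01	GAGCCACTCCACGCAC	reverse	948-963

[probes]
C380P01	FAM	BHQ1	CGCTTGTACTTCTGTGTCTCCCGGTCCCAATACTCC	380-415
C818P01	TET	BHQ1	AGRTCCTCGTTCAGGGCGATGTAATCCTTGC	818-848

[reactions]
HLA-C 001	C235F01	C439R01	C380P01	C798F01	C948R01	C818P01	Cw*0602,Cw*1801
HLA-C 002	C235F01	C439R02	C380P01	C798F01	C948R01	C818P01	Cw*0701,Cw*0702,Cw*0704
HLA-C 003	C242F01	C439R01	C380P01	C798F01	C948R01	C818P01	Cw*0401
HLA-C 004	C255F02	C439R02	C380P01	C798F01	C948R01	C818P01	Cw*0302,Cw*0304,Cw*0701,Cw*0702,Cw*0704,Cw*0802,Cw*1601
HLA-C 005	C806F02	C925R06	C818P01	C329F01	C427R01	C380P01	Cw*0210,Cw*0602
HLA-C 006	C806F03	C946R01	C818P01	C329F01	C427R01	C380P01	Cw*0602,Cw*0701,Cw*0702,Cw*1601
HLA-C 007	C806F04	C946R03	C818P01	C329F01	C427R01	C380P01	Cw*1701
HLA-C 008	C806F01	C946R02	C818P01	C329F01	C427R01	C380P01	Cw*0304
HLA-C 009	C799F01	C925R05	C818P01	C329F01	C427R01	C380P01	Cw*0704
HLA-C 010	C755F02	C925R03	C818P01	C329F01	C427R01	C380P01	Cw*0702
HLA-C 011	C799F01	C925R01	C818P01	C329F01	C427R01	C380P01	Cw*1601
HLA-C 012	C806F04	C925R02	C818P01	C329F01	C427R01	C380P01	Cw*0401,Cw*0802,Cw*1801
HLA-C 013	C255F01	C426R01	C380P01	C798F01	C948R01	C818P01	Cw*0210
HLA-C 014	C806F03	C946R02	C818P01	C329F01	C427R01	C380P01	Cw*0302
HLA-C 015	C755F01	C925R03	C818P01	C329F01	C427R01	C380P01	Cw*0302,Cw*0304,Cw*0701,Cw*1701
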